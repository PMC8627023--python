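"""Synthetic data: shifted two-domain feature tables and toy genome tracks.

Two generators cover everything the pipeline consumes.

:func:`generate_domains` emulates the statistical situation transfer
learning assumes: source and target records share a low-dimensional
latent factor structure that determines function, while the target
domain's observed features undergo a location/scale change (covariate
shift). Concretely, each record draws ``q`` latent factors ``f ~
N(0, I)``; features are ``x = Lambda f + eps``; the functional label is
Bernoulli with ``P(functional) = sigmoid(beta' f + b)`` in *both*
domains (the rule transfers); and target features are additionally
shifted by ``mean_shift`` and scaled by ``cov_scale``. Because the
label-bearing factors dominate the correlation structure while the
shift is (near) orthogonal to them, an embedding that preserves
variance and cancels the domain discrepancy retains the signal — the
premise under which transfer component analysis is expected to work.

:func:`generate_tracks` builds smooth pseudo-conservation tracks,
per-residue structure annotations and toy record catalogs with residue
mappings for exercising the feature extractor end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import GenomicInterval, MicroexonRecord, MicroindelRecord
from .tca import DomainDataset

# FEATURE_NAMES lives in features.py, which imports DomainDataset from
# tca.py; import lazily inside functions to keep the module graph acyclic.

N_LATENT_FACTORS = 4


def _default_loadings(n_features: int, q: int = N_LATENT_FACTORS) -> np.ndarray:
    """Deterministic factor-loading matrix.

    Each factor loads with magnitude 1.2 on every q-th feature
    (alternating sign along the feature axis) plus a small dense
    cross-loading, giving a few dominant correlated blocks the way
    redundant biological feature panels (conservation triples,
    class-probability triples) do.
    """
    loadings = np.zeros((n_features, q))
    for i in range(n_features):
        for j in range(q):
            if i % q == j:
                loadings[i, j] = 1.2 * (-1.0) ** (i // q)
            else:
                loadings[i, j] = 0.15 * (-1.0) ** (i + j)
    return loadings


def _default_factor_weights(q: int = N_LATENT_FACTORS) -> np.ndarray:
    # margin std ~6 => low Bayes error while keeping labels stochastic
    return 3.0 * np.array([1.0, -1.0] * (q // 2) + [1.0] * (q % 2))


@dataclass
class ShiftScenario:
    """Parameters of a two-domain covariate-shift simulation.

    ``mean_shift`` (scalar or per-feature vector) translates the target
    features; ``cov_scale`` multiplies their spread; ``noise_sd`` is
    i.i.d. observation noise added to both domains. ``label_weights``
    and ``label_intercept`` define the logistic rule on the latent
    factors shared by both domains; the target's labels are returned
    separately as hidden ground truth.
    """

    n_source: int = 400
    n_target: int = 400
    n_features: int = 25
    mean_shift: float | Sequence[float] = 1.0
    cov_scale: float = 1.2
    noise_sd: float = 0.3
    residual_sd: float = 0.6
    label_weights: np.ndarray | None = None
    label_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_source <= 0 or self.n_target <= 0:
            raise ValueError("domain sizes must be positive")
        if self.cov_scale <= 0:
            raise ValueError("cov_scale must be positive")
        if self.noise_sd < 0 or self.residual_sd < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def shift_vector(self) -> np.ndarray:
        shift = np.asarray(self.mean_shift, dtype=float)
        if shift.ndim == 0:
            shift = np.full(self.n_features, float(shift))
        if shift.shape != (self.n_features,):
            raise ValueError("mean_shift must be scalar or one value per feature")
        return shift

    @property
    def weights(self) -> np.ndarray:
        if self.label_weights is not None:
            w = np.asarray(self.label_weights, dtype=float)
            if w.shape != (N_LATENT_FACTORS,):
                raise ValueError(f"label_weights must have {N_LATENT_FACTORS} entries")
            return w
        return _default_factor_weights()


def _feature_columns(n_features: int) -> list[str]:
    from .features import FEATURE_NAMES

    if n_features == len(FEATURE_NAMES):
        return list(FEATURE_NAMES)
    return [f"f{i}" for i in range(n_features)]


def _draw_domain(
    rng: np.random.Generator, n: int, scenario: ShiftScenario
) -> tuple[np.ndarray, np.ndarray]:
    """One domain's pre-shift features and labels from the shared rule."""
    loadings = _default_loadings(scenario.n_features)
    factors = rng.standard_normal((n, N_LATENT_FACTORS))
    X = factors @ loadings.T
    X += scenario.residual_sd * rng.standard_normal(X.shape)
    margin = factors @ scenario.weights + scenario.label_intercept
    p_functional = 1.0 / (1.0 + np.exp(-margin))
    labels = (rng.random(n) < p_functional).astype(int)
    return X, labels


def generate_domains(
    scenario: ShiftScenario,
) -> tuple[DomainDataset, DomainDataset, np.ndarray]:
    """Draw a (source, target, hidden target labels) triple.

    Deterministic per seed. The source dataset carries its labels; the
    target's are returned separately so the pipeline cannot see them.
    """
    rng = np.random.default_rng(scenario.seed)
    columns = _feature_columns(scenario.n_features)

    Xs, ys = _draw_domain(rng, scenario.n_source, scenario)
    Xs = Xs + scenario.noise_sd * rng.standard_normal(Xs.shape)

    Xt, yt = _draw_domain(rng, scenario.n_target, scenario)
    Xt = scenario.cov_scale * Xt + scenario.shift_vector
    Xt = Xt + scenario.noise_sd * rng.standard_normal(Xt.shape)

    source = DomainDataset(
        matrix=pd.DataFrame(Xs, columns=columns), labels=ys, domain_tag="source"
    )
    target = DomainDataset(
        matrix=pd.DataFrame(Xt, columns=columns), labels=None, domain_tag="target"
    )
    return source, target, yt


# ---------------------------------------------------------------------------
# genome-track fixtures


@dataclass
class SyntheticTracks:
    """Toy genome: conservation track, proteins, records with mappings."""

    conservation: "object"  # ArrayConservationTrack
    proteins: dict[str, list]
    microexons: list[MicroexonRecord] = field(default_factory=list)
    microindels: list[MicroindelRecord] = field(default_factory=list)
    exon_mappings: list = field(default_factory=list)
    indel_mappings: list = field(default_factory=list)


def _smooth_noise(rng: np.random.Generator, size: int, window: int = 25) -> np.ndarray:
    raw = rng.standard_normal(size + window)
    kernel = np.ones(window) / window
    return np.convolve(raw, kernel, mode="valid")[:size]


def generate_tracks(
    n_chroms: int = 2,
    chrom_length: int = 5000,
    n_records: int = 20,
    seed: int = 0,
) -> SyntheticTracks:
    """Build a deterministic toy genome for the feature extractor.

    Conservation is autocorrelated noise rescaled to a phyloP-like
    range; residue class probabilities are Dirichlet draws; disorder
    lies in [0, 1] and ASA in [0, 100]. Records are frame-preserving
    (lengths in {3, 6, ..., 30}) with valid residue mappings.
    """
    from .features import ArrayConservationTrack, ResidueAnnotation, ResidueMapping

    if n_chroms <= 0 or chrom_length <= 0 or n_records <= 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    arrays = {
        chrom: np.clip(4.0 * _smooth_noise(rng, chrom_length) + 1.0, -3.0, 7.0)
        for chrom in chroms
    }
    conservation = ArrayConservationTrack(arrays)

    tracks = SyntheticTracks(conservation=conservation, proteins={})
    eligible_lengths = np.arange(3, 31, 3)
    for i in range(n_records):
        protein_id = f"prot{i}"
        protein_length = int(rng.integers(60, 300))
        probs = rng.dirichlet(np.array([2.0, 1.5, 1.0]), size=protein_length)
        disorder = np.clip(
            _smooth_noise(rng, protein_length, window=9) * 0.8 + 0.5, 0.0, 1.0
        )
        asa = np.clip(
            35.0 + 25.0 * _smooth_noise(rng, protein_length, window=9), 0.0, 100.0
        )
        tracks.proteins[protein_id] = [
            ResidueAnnotation(
                prob_C=float(p[0]), prob_H=float(p[1]), prob_E=float(p[2]),
                disorder=float(d), asa=float(a),
            )
            for p, d, a in zip(probs, disorder, asa)
        ]

        chrom = chroms[int(rng.integers(n_chroms))]
        length = int(rng.choice(eligible_lengths))
        n_res = length // 3
        res_start = int(rng.integers(0, protein_length - n_res + 1))
        start = int(rng.integers(50, chrom_length - 50 - length))

        if i % 3 == 2:  # every third record is an indel, alternating kind
            if i % 2 == 0:
                record: MicroexonRecord | MicroindelRecord = MicroindelRecord(
                    GenomicInterval(chrom, start, start + length),
                    "deletion", length, "unknown", name=f"indel{i}",
                )
                mapping = ResidueMapping(protein_id, res_start, res_start + n_res)
            else:
                record = MicroindelRecord(
                    GenomicInterval(chrom, start, start),
                    "insertion", length, "unknown", name=f"indel{i}",
                )
                insertion_point = int(rng.integers(1, protein_length))
                mapping = ResidueMapping(protein_id, insertion_point, insertion_point)
            tracks.microindels.append(record)
            tracks.indel_mappings.append(mapping)
        else:
            record = MicroexonRecord(
                GenomicInterval(chrom, start, start + length),
                length, name=f"exon{i}",
            )
            tracks.microexons.append(record)
            tracks.exon_mappings.append(
                ResidueMapping(protein_id, res_start, res_start + n_res)
            )
    return tracks
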