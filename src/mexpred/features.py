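"""The 25-feature representation of a microexon or microindel.

Each record is described at the gene level (its length and per-base
conservation over the affected span plus a flank of ``n_window`` bases)
and at the protein level (secondary-structure class probabilities,
predicted-class composition, disorder, accessible surface area over the
encoded residues plus a flank of ``n_window`` residues, and three length
features: protein length and distances of the encoded peptide to the N-
and C-terminus).

Per-base conservation (phyloP-style) and per-residue structure
annotations come from pluggable providers so that real tracks (bigWig,
flat tables) and synthetic ones share one code path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .catalog import DataError, MicroexonRecord, MicroindelRecord
from .tca import DomainDataset

logger = logging.getLogger(__name__)

DEFAULT_N_WINDOW = 2

SS_CLASSES = ("C", "H", "E")  # random coil, alpha-helix, beta-sheet

#: Canonical order of the 25 features; every producer and consumer in the
#: package uses exactly this order.
FEATURE_NAMES: tuple[str, ...] = (
    "record_length",
    "cons_max", "cons_min", "cons_mean",
    "ss_prob_max_C", "ss_prob_min_C", "ss_prob_mean_C",
    "ss_prob_max_H", "ss_prob_min_H", "ss_prob_mean_H",
    "ss_prob_max_E", "ss_prob_min_E", "ss_prob_mean_E",
    "ss_pred_frac_C", "ss_pred_frac_H", "ss_pred_frac_E",
    "dis_max", "dis_min", "dis_mean",
    "asa_max", "asa_min", "asa_mean",
    "protein_length", "dist_to_start", "dist_to_end",
)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 25


class ConservationProvider(Protocol):
    """Deterministic per-base conservation lookup.

    ``score`` returns a real conservation value for a 0-based position,
    or NaN when the position (or chromosome) is not covered.
    """

    def score(self, chrom: str, pos: int) -> float: ...


class ConstantConservation:
    """Provider returning one fixed value everywhere (tests, ablations)."""

    def __init__(self, value: float):
        self.value = float(value)

    def score(self, chrom: str, pos: int) -> float:
        return self.value


class ArrayConservationTrack:
    """In-memory track: one score array per chromosome, NaN off the ends."""

    def __init__(self, arrays: Mapping[str, np.ndarray]):
        self.arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}

    def score(self, chrom: str, pos: int) -> float:
        arr = self.arrays.get(chrom)
        if arr is None or pos < 0 or pos >= arr.size:
            return math.nan
        return float(arr[pos])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ArrayConservationTrack":
        """Load a flat track with columns ``chrom, pos, score`` (0-based)."""
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = [c for c in ("chrom", "pos", "score") if c not in table.columns]
        if missing:
            raise DataError(f"{path}: missing track columns {missing}")
        arrays: dict[str, np.ndarray] = {}
        for chrom, group in table.groupby("chrom"):
            size = int(group["pos"].max()) + 1
            arr = np.full(size, np.nan)
            arr[group["pos"].to_numpy(dtype=int)] = group["score"].to_numpy(dtype=float)
            arrays[str(chrom)] = arr
        return cls(arrays)

    def to_tsv(self, path: str | Path) -> None:
        frames = [
            pd.DataFrame({"chrom": chrom, "pos": np.arange(arr.size), "score": arr})
            for chrom, arr in sorted(self.arrays.items())
        ]
        pd.concat(frames, ignore_index=True).dropna().to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


class BigWigConservation:
    """Adapter over a bigWig conservation track (phyloP and friends)."""

    def __init__(self, path: str | Path):
        import pyBigWig  # optional dependency, only needed for real tracks

        self._bw = pyBigWig.open(str(path))

    def score(self, chrom: str, pos: int) -> float:
        if chrom not in self._bw.chroms() or pos < 0:
            return math.nan
        if pos >= self._bw.chroms(chrom):
            return math.nan
        value = self._bw.values(chrom, pos, pos + 1)[0]
        return math.nan if value is None else float(value)

    def close(self) -> None:
        self._bw.close()


@dataclass(frozen=True)
class ResidueAnnotation:
    """Predicted structural state of one residue.

    ``prob_C``, ``prob_H``, ``prob_E`` are secondary-structure class
    probabilities (coil, helix, sheet) that sum to 1; ``disorder`` is the
    intrinsic-disorder probability; ``asa`` the accessible surface area
    in provider units. ``pred_class`` defaults to the argmax class
    (ties broken in C, H, E order).
    """

    prob_C: float
    prob_H: float
    prob_E: float
    disorder: float
    asa: float
    pred_class: str = ""

    def __post_init__(self) -> None:
        total = self.prob_C + self.prob_H + self.prob_E
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"class probabilities sum to {total}, expected 1")
        if self.asa < 0:
            raise ValueError("asa must be non-negative")
        if self.pred_class == "":
            probs = (self.prob_C, self.prob_H, self.prob_E)
            object.__setattr__(self, "pred_class", SS_CLASSES[int(np.argmax(probs))])
        elif self.pred_class not in SS_CLASSES:
            raise ValueError(f"invalid pred_class {self.pred_class!r}")


@dataclass(frozen=True)
class ResidueMapping:
    """Where a record's encoded peptide sits within its protein.

    ``res_start``/``res_end`` are 0-based half-open residue indices of
    the encoded peptide; insertions map to a zero-length span at the
    insertion point (``res_end == res_start``).
    """

    protein_id: str
    res_start: int
    res_end: int

    def __post_init__(self) -> None:
        if self.res_start < 0 or self.res_end < self.res_start:
            raise ValueError(
                f"invalid residue span [{self.res_start}, {self.res_end})"
            )


# ---------------------------------------------------------------------------
# windows


def conservation_positions(
    record: MicroindelRecord | MicroexonRecord, n_window: int = DEFAULT_N_WINDOW
) -> list[int]:
    """0-based positions queried for the conservation features.

    Deletions and microexons cover their span plus ``n_window`` flanking
    bases on each side (``length + 2 n_window`` positions); insertions
    cover the two bases around the insertion point plus the flanks
    (``2 + 2 n_window`` positions). Positions may be negative near the
    chromosome start; the provider reports those as missing.
    """
    if n_window < 0:
        raise ValueError("n_window must be >= 0")
    iv = record.interval
    if isinstance(record, MicroindelRecord) and record.kind == "insertion":
        return list(range(iv.start - 1 - n_window, iv.start + 1 + n_window))
    return list(range(iv.start - n_window, iv.end + n_window))


def conservation_window(
    record: MicroindelRecord | MicroexonRecord,
    provider: ConservationProvider,
    n_window: int = DEFAULT_N_WINDOW,
) -> tuple[float, float, float]:
    """(max, min, mean) conservation over the record's query window.

    Missing positions are ignored; if every queried position is missing
    the triple is NaN and the caller imputes downstream.
    """
    chrom = record.interval.chrom
    values = np.array(
        [provider.score(chrom, pos) for pos in conservation_positions(record, n_window)]
    )
    values = values[np.isfinite(values)]
    if values.size == 0:
        return (math.nan, math.nan, math.nan)
    return (float(values.max()), float(values.min()), float(values.mean()))


def residue_window(
    mapping: ResidueMapping,
    annotations: Sequence[ResidueAnnotation],
    n_window: int = DEFAULT_N_WINDOW,
) -> list[ResidueAnnotation]:
    """Annotations for the encoded residues plus ``n_window`` on each side.

    Zero-length (insertion) mappings take the two residues flanking the
    insertion point plus the flanks, mirroring the DNA-level rule. The
    window is truncated at the protein boundaries; a mapping outside the
    protein raises.
    """
    if n_window < 0:
        raise ValueError("n_window must be >= 0")
    n = len(annotations)
    if mapping.res_start > n or mapping.res_end > n:
        raise DataError(
            f"{mapping.protein_id}: residue span [{mapping.res_start}, "
            f"{mapping.res_end}) outside protein of length {n}"
        )
    if mapping.res_end == mapping.res_start:
        lo = mapping.res_start - 1 - n_window
        hi = mapping.res_start + 1 + n_window
    else:
        lo = mapping.res_start - n_window
        hi = mapping.res_end + n_window
    return list(annotations[max(lo, 0):min(hi, n)])


# ---------------------------------------------------------------------------
# extraction


def _triple(values: np.ndarray) -> tuple[float, float, float]:
    if values.size == 0 or not np.isfinite(values).all():
        values = values[np.isfinite(values)]
    if values.size == 0:
        return (math.nan, math.nan, math.nan)
    return (float(values.max()), float(values.min()), float(values.mean()))


def extract_features(
    record: MicroindelRecord | MicroexonRecord,
    mapping: ResidueMapping,
    annotations: Sequence[ResidueAnnotation],
    conservation: ConservationProvider,
    n_window: int = DEFAULT_N_WINDOW,
) -> np.ndarray:
    """Compute the full 25-feature vector for one record.

    Returns the vector in :data:`FEATURE_NAMES` order. Provider gaps
    yield NaN entries that are median-imputed later in the pipeline.
    """
    length = (
        record.indel_length
        if isinstance(record, MicroindelRecord)
        else record.exon_length
    )
    out = np.full(N_FEATURES, np.nan)
    out[0] = length
    out[1:4] = conservation_window(record, conservation, n_window)

    window = residue_window(mapping, annotations, n_window)
    if window:
        probs = np.array([[a.prob_C, a.prob_H, a.prob_E] for a in window])
        for j, cls in enumerate(SS_CLASSES):
            out[4 + 3 * j:7 + 3 * j] = _triple(probs[:, j])
        classes = [a.pred_class for a in window]
        for j, cls in enumerate(SS_CLASSES):
            out[13 + j] = classes.count(cls) / len(classes)
        out[16:19] = _triple(np.array([a.disorder for a in window]))
        out[19:22] = _triple(np.array([a.asa for a in window]))
    protein_length = len(annotations)
    out[22] = protein_length
    out[23] = mapping.res_start
    out[24] = protein_length - max(mapping.res_end, mapping.res_start)
    return out


def extract_feature_table(
    records: Sequence[MicroindelRecord | MicroexonRecord],
    mappings: Sequence[ResidueMapping],
    proteins: Mapping[str, Sequence[ResidueAnnotation]],
    conservation: ConservationProvider,
    n_window: int = DEFAULT_N_WINDOW,
) -> pd.DataFrame:
    """Feature matrix for a batch of records (one row per record)."""
    if len(records) != len(mappings):
        raise ValueError("records and mappings must be parallel")
    rows = []
    index = []
    for i, (record, mapping) in enumerate(zip(records, mappings)):
        annotations = proteins.get(mapping.protein_id)
        if annotations is None:
            raise DataError(f"no annotations for protein {mapping.protein_id!r}")
        rows.append(extract_features(record, mapping, annotations, conservation, n_window))
        index.append(record.name or f"record{i}")
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES), index=index)


# ---------------------------------------------------------------------------
# feature-table TSV dialect


def write_feature_table(
    features: pd.DataFrame,
    path: str | Path,
    labels: Sequence[int] | None = None,
) -> None:
    """Write a 25-column feature table (plus optional binary label column).

    Missing values are serialized as ``NA``.
    """
    if list(features.columns) != list(FEATURE_NAMES):
        raise DataError("feature table must have exactly the 25 canonical columns")
    table = features.copy()
    if labels is not None:
        if len(labels) != len(table):
            raise ValueError("labels length must match features")
        table["label"] = np.asarray(labels, dtype=int)
    table.to_csv(path, sep="\t", index_label="record_id", na_rep="NA")


def read_feature_table(path: str | Path, domain_tag: str = "source") -> DomainDataset:
    """Read a feature table written by :func:`write_feature_table`.

    The header must name exactly the 25 canonical features (plus the
    optional ``label`` column); any deviation is fatal, with the first
    offending column named.
    """
    table = pd.read_csv(path, sep="\t", index_col="record_id", na_values=["NA"])
    has_label = "label" in table.columns
    expected = list(FEATURE_NAMES) + (["label"] if has_label else [])
    got = list(table.columns)
    for i, name in enumerate(expected):
        if i >= len(got) or got[i] != name:
            offending = got[i] if i < len(got) else "<missing>"
            raise DataError(
                f"{path}: feature-table header mismatch at column "
                f"{i + 1}: expected {name!r}, found {offending!r}"
            )
    if len(got) > len(expected):
        raise DataError(
            f"{path}: unexpected extra column {got[len(expected)]!r}"
        )
    labels = table.pop("label").to_numpy(dtype=int) if has_label else None
    return DomainDataset(matrix=table, labels=labels, domain_tag=domain_tag)


# ---------------------------------------------------------------------------
# residue-annotation TSV dialect


def write_residue_annotations(
    proteins: Mapping[str, Sequence[ResidueAnnotation]], path: str | Path
) -> None:
    """One row per residue: protein_id, index, probs, pred_class, disorder, asa."""
    rows = []
    for pid in sorted(proteins):
        for i, a in enumerate(proteins[pid]):
            rows.append(
                (pid, i, a.prob_C, a.prob_H, a.prob_E, a.pred_class, a.disorder, a.asa)
            )
    pd.DataFrame(
        rows,
        columns=[
            "protein_id", "index", "prob_C", "prob_H", "prob_E",
            "pred_class", "disorder", "asa",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_residue_annotations(
    path: str | Path,
) -> dict[str, list[ResidueAnnotation]]:
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = ["protein_id", "index", "prob_C", "prob_H", "prob_E", "disorder", "asa"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DataError(f"{path}: missing residue-annotation columns {missing}")
    proteins: dict[str, list[ResidueAnnotation]] = {}
    for pid, group in table.groupby("protein_id", sort=False):
        group = group.sort_values("index")
        if not (group["index"].to_numpy() == np.arange(len(group))).all():
            raise DataError(f"{path}: protein {pid} has gaps in residue indices")
        proteins[str(pid)] = [
            ResidueAnnotation(
                prob_C=row.prob_C, prob_H=row.prob_H, prob_E=row.prob_E,
                disorder=row.disorder, asa=row.asa,
                pred_class=str(getattr(row, "pred_class", "") or ""),
            )
            for row in group.itertuples(index=False)
        ]
    return proteins


def read_residue_mappings(path: str | Path) -> list[ResidueMapping]:
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = ["protein_id", "res_start", "res_end"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DataError(f"{path}: missing mapping columns {missing}")
    return [
        ResidueMapping(str(r.protein_id), int(r.res_start), int(r.res_end))
        for r in table.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# preprocessing (imputation + standardization, fit on the source domain)


class Preprocessor:
    """Median imputation followed by per-feature z-scoring.

    Both steps are fit on the labeled source domain only and then
    applied to source and target alike, so target statistics never leak
    into the scaling. Kernel methods on mixed-unit features require the
    scaling; the median is a robust, deterministic imputation.
    """

    def __init__(self) -> None:
        self.medians_: pd.Series | None = None
        self.means_: pd.Series | None = None
        self.stds_: pd.Series | None = None

    def fit(self, features: pd.DataFrame) -> "Preprocessor":
        self.medians_ = features.median(skipna=True)
        filled = features.fillna(self.medians_)
        self.means_ = filled.mean()
        stds = filled.std(ddof=0)
        self.stds_ = stds.mask(stds < 1e-12, 1.0)  # constant columns pass through
        return self

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        if self.medians_ is None:
            raise RuntimeError("Preprocessor not fitted")
        filled = features.fillna(self.medians_)
        if filled.isna().any().any():
            # medians can be NaN if a source column was entirely missing
            raise DataError("unimputable column: all source values missing")
        return (filled - self.means_) / self.stds_

    def fit_transform(self, features: pd.DataFrame) -> pd.DataFrame:
        return self.fit(features).transform(features)
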