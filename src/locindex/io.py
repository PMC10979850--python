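"""Reading, normalizing, filtering and aligning per-fraction transcript quantifications.

Quantification tables are tab-separated, RSEM-isoform-results compatible:
a header row naming at least transcript id, length, effective length and
expected count columns (case-insensitive aliases accepted). Whole-cell,
nuclear and cytosolic samples of the same specimen are combined into a
:class:`MatchedTriplet` of aligned FPKM vectors, the input of the cytosolic
volume-fraction regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class QuantFormatError(ValueError):
    """A quantification table does not conform to the expected format."""


class QuantDataError(ValueError):
    """A quantification table is structurally valid but its data are unusable."""


class Fraction(str, Enum):
    """Cellular fraction a library was sequenced from."""

    WHOLE = "whole"
    NUCLEAR = "nuclear"
    CYTOSOLIC = "cytosolic"


#: Case-insensitive aliases for the required/optional table columns.
COLUMN_ALIASES = {
    "transcript_id": {"transcript_id", "transcript", "tx_id", "isoform_id", "target_id"},
    "gene_id": {"gene_id", "gene"},
    "length": {"length", "len"},
    "effective_length": {"effective_length", "eff_length", "efflength", "eff_len"},
    "expected_count": {"expected_count", "est_counts", "count", "counts"},
    "tpm": {"tpm"},
    "fpkm": {"fpkm"},
}

REQUIRED_COLUMNS = ("transcript_id", "length", "effective_length", "expected_count")


@dataclass
class FractionSample:
    """Per-transcript quantifications of one sequencing library.

    Parameters
    ----------
    fraction
        Which cellular fraction the library measures.
    records
        DataFrame indexed by transcript id with columns ``length``,
        ``effective_length``, ``expected_count`` and (after normalization)
        ``fpkm`` and ``cpm``.
    depth
        Total assigned reads. Derived as the sum of expected counts over all
        transcripts (before any filtering) unless supplied explicitly.
    replicate_id
        Free-form replicate label.
    """

    fraction: Fraction
    records: pd.DataFrame
    depth: float | None = None
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.fraction = Fraction(self.fraction)
        if not self.records.index.is_unique:
            dup = self.records.index[self.records.index.duplicated()][0]
            raise QuantDataError(f"duplicate transcript_id {dup!r} in {self.fraction.value} sample")
        if self.depth is None and len(self.records):
            self.depth = float(self.records["expected_count"].sum())
        if self.depth is not None and self.depth <= 0:
            self.depth = None  # empty/zero library: depth is undefined
        self._normalize()

    def _normalize(self) -> None:
        """(Re)compute FPKM and CPM from counts, lengths and depth."""
        if self.depth is None or not len(self.records):
            return
        counts = self.records["expected_count"].to_numpy(float)
        eff = self.records["effective_length"].to_numpy(float)
        ann = self.records["length"].to_numpy(float)
        # RSEM convention: FPKM over effective length; fall back to the
        # annotated length where the effective length is missing/zero.
        lengths = np.where(eff > 0, eff, ann)
        self.records = self.records.assign(
            fpkm=compute_fpkm(counts, lengths, self.depth),
            cpm=compute_cpm(counts, self.depth),
        )

    @property
    def transcript_ids(self) -> pd.Index:
        return self.records.index

    def counts(self, ids: Sequence[str]) -> np.ndarray:
        """Expected counts for ``ids``; transcripts absent from the library count 0."""
        return (
            self.records["expected_count"].reindex(ids, fill_value=0.0).to_numpy(float)
        )


@dataclass
class MatchedTriplet:
    """Aligned whole/nuclear/cytosolic FPKM vectors over a common transcript set."""

    transcript_ids: list[str]
    fpkm_w: np.ndarray
    fpkm_n: np.ndarray
    fpkm_c: np.ndarray

    def __post_init__(self) -> None:
        self.fpkm_w = np.asarray(self.fpkm_w, float)
        self.fpkm_n = np.asarray(self.fpkm_n, float)
        self.fpkm_c = np.asarray(self.fpkm_c, float)
        t = len(self.transcript_ids)
        if not (len(self.fpkm_w) == len(self.fpkm_n) == len(self.fpkm_c) == t):
            raise QuantDataError("triplet vectors must share the transcript axis")
        if t < 1:
            raise QuantDataError("empty triplet")
        allzero = (self.fpkm_w == 0) & (self.fpkm_n == 0) & (self.fpkm_c == 0)
        if allzero.any():
            raise QuantDataError(
                f"{int(allzero.sum())} transcripts have zero FPKM in all three fractions"
            )

    def __len__(self) -> int:
        return len(self.transcript_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpkm_w": self.fpkm_w, "fpkm_n": self.fpkm_n, "fpkm_c": self.fpkm_c},
            index=pd.Index(self.transcript_ids, name="transcript_id"),
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "MatchedTriplet":
        df = pd.read_csv(path, sep="\t", index_col="transcript_id")
        return cls(list(df.index), df["fpkm_w"].values, df["fpkm_n"].values, df["fpkm_c"].values)


def _resolve_columns(columns: Iterable[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in columns:
        key = col.strip().lower().replace(" ", "_").lstrip("#")
        for canonical, aliases in COLUMN_ALIASES.items():
            if key in aliases and canonical not in mapping:
                mapping[canonical] = col
    return mapping


def read_quant_table(
    path: str | Path,
    fraction: Fraction | str,
    replicate_id: str = "rep1",
    depth: float | None = None,
) -> FractionSample:
    """Read one RSEM-style quantification table into a :class:`FractionSample`.

    Raises
    ------
    QuantFormatError
        If a required column is missing (the error names the column).
    QuantDataError
        On duplicate transcript ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment=None)
    mapping = _resolve_columns(df.columns)
    for col in REQUIRED_COLUMNS:
        if col not in mapping:
            raise QuantFormatError(f"{path}: missing required column {col!r}")
    keep = {canonical: df[orig] for canonical, orig in mapping.items()}
    out = pd.DataFrame(keep).set_index("transcript_id")
    for col in ("length", "effective_length", "expected_count"):
        out[col] = pd.to_numeric(out[col], errors="raise")
    if (out["length"] < 1).any():
        raise QuantDataError(f"{path}: transcript lengths must be >= 1 nt")
    if (out["expected_count"] < 0).any():
        raise QuantDataError(f"{path}: negative expected counts")
    return FractionSample(Fraction(fraction), out, depth=depth, replicate_id=replicate_id)


def compute_fpkm(
    counts: np.ndarray, lengths: np.ndarray, depth: float
) -> np.ndarray:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``fpkm[i] = counts[i] / (lengths[i] / 1e3) / (depth / 1e6)``
    """
    counts = np.asarray(counts, float)
    lengths = np.asarray(lengths, float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have the same shape")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if (lengths <= 0).any():
        raise ValueError("all transcript lengths must be positive")
    return counts / (lengths / 1e3) / (depth / 1e6)


def compute_cpm(counts: np.ndarray, depth: float) -> np.ndarray:
    """Counts per million mapped reads."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    return np.asarray(counts, float) / (depth / 1e6)


def filter_expression(
    w: FractionSample,
    n: FractionSample,
    c: FractionSample,
    cpm_threshold: float = 1.0,
    excluded_ids: Iterable[str] = (),
) -> set[str]:
    """Expression-detection filter over the union of transcript ids.

    A transcript is retained iff its whole-cell CPM is at or above the
    threshold AND at least one of the nuclear / cytosolic CPMs is too, and
    it is not in ``excluded_ids`` (typically the mitochondrial transcripts,
    which do not partition between nucleus and cytosol).

    Transcripts absent from a sample are treated as count 0 in that sample.
    """
    if any(s.depth is None for s in (w, n, c)):
        raise QuantDataError("cannot filter: a sample has undefined depth")
    universe = w.transcript_ids.union(n.transcript_ids).union(c.transcript_ids)
    ids = np.asarray(universe)
    cpm_w = compute_cpm(w.counts(ids), w.depth)
    cpm_n = compute_cpm(n.counts(ids), n.depth)
    cpm_c = compute_cpm(c.counts(ids), c.depth)
    keep = (cpm_w >= cpm_threshold) & ((cpm_n >= cpm_threshold) | (cpm_c >= cpm_threshold))
    retained = set(ids[keep]) - set(excluded_ids)
    return retained


def detected_in_all_replicates(
    samples_by_fraction: dict[Fraction | str, Sequence[FractionSample]],
) -> set[str]:
    """Replicate-consistency filter: transcripts detected (count > 0) in every
    replicate of every fraction. Optional substitute for reproducibility
    filtering when replicates are available."""
    retained: set[str] | None = None
    for _, samples in samples_by_fraction.items():
        for s in samples:
            present = set(s.records.index[s.records["expected_count"] > 0])
            retained = present if retained is None else retained & present
    return retained or set()


def build_triplet(
    w: FractionSample,
    n: FractionSample,
    c: FractionSample,
    retained: Iterable[str],
) -> MatchedTriplet:
    """Align the three samples over ``retained`` into a regression-ready triplet.

    Transcripts are ordered lexicographically; FPKMs are recomputed from
    counts, effective lengths and pre-filter depths so that all three vectors
    share a single normalization convention.
    """
    ids = sorted(retained)
    if not ids:
        raise QuantDataError("empty retained set")
    missing = [i for i in ids if i not in w.transcript_ids]
    if missing:
        raise QuantDataError(
            f"{len(missing)} retained transcripts absent from the whole-cell sample "
            f"(first: {missing[0]!r})"
        )
    if len(ids) < 50:
        logger.warning(
            "triplet has only %d transcripts; beta estimates below ~50 transcripts "
            "are weakly identified", len(ids),
        )

    def fpkms(sample: FractionSample) -> np.ndarray:
        counts = sample.counts(ids)
        eff = sample.records["effective_length"].reindex(ids).to_numpy(float)
        ann = sample.records["length"].reindex(ids).to_numpy(float)
        # ids may be missing from this fraction: borrow the whole-cell length
        ann_w = w.records["length"].reindex(ids).to_numpy(float)
        lengths = np.where(np.isfinite(eff) & (eff > 0), eff, np.where(np.isfinite(ann), ann, ann_w))
        return compute_fpkm(counts, lengths, sample.depth)

    return MatchedTriplet(ids, fpkms(w), fpkms(n), fpkms(c))


def pool_pseudobulk(samples: Sequence[FractionSample]) -> FractionSample:
    """Sum per-transcript counts over libraries of the same fraction.

    This is the pseudo-bulk construction for fractionated single-cell data:
    cells are merged per fraction into one bulk-like library, with depth the
    summed depth and FPKM/CPM recomputed.
    """
    if not samples:
        raise ValueError("pool_pseudobulk requires at least one sample")
    fractions = {s.fraction for s in samples}
    if len(fractions) != 1:
        raise ValueError(f"cannot pool samples from mixed fractions: {sorted(f.value for f in fractions)}")
    counts = samples[0].records["expected_count"]
    for s in samples[1:]:  # outer-join alignment; absent transcripts count 0
        counts = counts.add(s.records["expected_count"], fill_value=0.0)
    all_ids = counts.index
    first = samples[0]

    def meta(col: str) -> pd.Series:
        out = samples[0].records[col].reindex(all_ids)
        for s in samples[1:]:
            out = out.fillna(s.records[col].reindex(all_ids))
        return out

    records = pd.DataFrame(
        {
            "length": meta("length"),
            "effective_length": meta("effective_length"),
            "expected_count": counts,
        }
    )
    if "gene_id" in first.records.columns:
        records["gene_id"] = meta("gene_id")
    return FractionSample(first.fraction, records, replicate_id="pseudobulk")
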