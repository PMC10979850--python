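"""Per-transcript localization indices and downstream summaries.

The localization index of transcript ``x`` is the estimated fraction of its
RNA molecules residing in the cytosol,

    LI(x) = beta * FPKM_c(x) / ((1 - beta) * FPKM_n(x) + beta * FPKM_c(x))

where ``beta`` is the cytosolic volume fraction of the sample. At
``beta = 0.5`` this reduces to the "naive" index ``FPKM_c / (FPKM_n +
FPKM_c)``, which under-estimates the cytosolic fraction whenever
``beta > 0.5`` and over-estimates it when ``beta < 0.5``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MatchedTriplet, QuantDataError

__all__ = [
    "Label",
    "LocalizationTable",
    "classify",
    "compute_localization_table",
    "consistency_summary",
    "enrichment_ratio",
    "expected_fraction_counts",
    "localization_index",
    "naive_localization_index",
    "replicate_consensus",
    "strong_localizers",
]


class Label(str, Enum):
    NUCLEAR = "nuclear"
    CYTOSOLIC = "cytosolic"
    INTERMEDIATE = "intermediate"
    UNDEFINED = "undefined"


def localization_index(fpkm_n, fpkm_c, beta: float):
    """Fraction of a transcript's molecules in the cytosol.

    Accepts scalars or aligned arrays. Where both fraction FPKMs are zero the
    index is undefined: NaN is returned and a warning is emitted (such
    transcripts cannot occur after expression filtering, but are handled
    safely).
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie strictly inside (0, 1)")
    n = np.asarray(fpkm_n, float)
    c = np.asarray(fpkm_c, float)
    if (n < 0).any() or (c < 0).any():
        raise ValueError("FPKM values must be non-negative")
    num = beta * c
    den = (1.0 - beta) * n + num
    undefined = den == 0
    if undefined.any():
        warnings.warn(
            f"{int(np.sum(undefined))} transcript(s) with zero FPKM in both "
            "fractions: localization index undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        out = np.where(undefined, np.nan, num / np.where(undefined, 1.0, den))
    return float(out) if out.ndim == 0 else out


def naive_localization_index(fpkm_n, fpkm_c):
    """``FPKM_c / (FPKM_n + FPKM_c)`` — correct only when beta = 0.5."""
    return localization_index(fpkm_n, fpkm_c, beta=0.5)


def expected_fraction_counts(
    molecules: Sequence[float], lengths: Sequence[float], depth: float
) -> np.ndarray:
    """Expected read counts of a fraction sequenced to ``depth`` reads.

    Reads are assigned proportionally to molecule count times transcript
    length: ``r(i) = depth * m_i * l_i / sum_j m_j * l_j``.
    """
    m = np.asarray(molecules, float)
    l = np.asarray(lengths, float)
    if m.shape != l.shape:
        raise ValueError("molecules and lengths must be aligned")
    if (l <= 0).any():
        raise ValueError("lengths must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    weight = m * l
    total = weight.sum()
    if total <= 0:
        raise ValueError("at least one molecule is required")
    return depth * weight / total


def classify(li, lower: float = 0.4, upper: float = 0.6):
    """Compartment preference from the localization index.

    ``li < lower`` is nuclear, ``li > upper`` cytosolic, anything between is
    intermediate; NaN (undefined index) maps to undefined. Vectorized.
    """
    if not 0.0 <= lower < upper <= 1.0:
        raise ValueError("need 0 <= lower < upper <= 1")
    arr = np.asarray(li, float)
    out = np.empty(arr.shape, dtype=object)
    out[...] = Label.INTERMEDIATE
    out[arr < lower] = Label.NUCLEAR
    out[arr > upper] = Label.CYTOSOLIC
    out[np.isnan(arr)] = Label.UNDEFINED
    return out.item() if arr.ndim == 0 else out


@dataclass
class LocalizationTable:
    """Localization indices of one sample: DataFrame indexed by transcript id
    with columns ``li``, ``naive_li``, ``label``."""

    sample_id: str
    beta_used: float
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if not 0.0 < self.beta_used < 1.0:
            raise ValueError("beta_used must lie in (0, 1)")
        if not self.records.index.is_unique:
            raise QuantDataError("duplicate transcript ids in localization table")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.records.index

    def defined(self) -> pd.DataFrame:
        return self.records[self.records["label"] != Label.UNDEFINED]

    def write(self, path: str | Path) -> None:
        out = self.records.copy()
        out["label"] = [Label(x).value for x in out["label"]]
        out["beta_used"] = self.beta_used
        out["sample_id"] = self.sample_id
        out.to_csv(path, sep="\t", index_label="transcript_id")

    @classmethod
    def read(cls, path: str | Path) -> "LocalizationTable":
        df = pd.read_csv(path, sep="\t", index_col="transcript_id")
        beta = float(df["beta_used"].iloc[0])
        sample = str(df["sample_id"].iloc[0])
        records = df[["li", "naive_li"]].copy()
        records["label"] = [Label(x) for x in df["label"]]
        return cls(sample, beta, records)


def compute_localization_table(
    triplet: MatchedTriplet,
    beta: float,
    sample_id: str = "sample",
    lower: float = 0.4,
    upper: float = 0.6,
) -> LocalizationTable:
    """Localization and naive indices for every transcript of a triplet."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        li = localization_index(triplet.fpkm_n, triplet.fpkm_c, beta)
        naive = naive_localization_index(triplet.fpkm_n, triplet.fpkm_c)
    records = pd.DataFrame(
        {"li": li, "naive_li": naive, "label": classify(li, lower, upper)},
        index=pd.Index(triplet.transcript_ids, name="transcript_id"),
    )
    return LocalizationTable(sample_id, beta, records)


def replicate_consensus(
    tables: Sequence[LocalizationTable],
    lower: float = 0.4,
    upper: float = 0.6,
) -> LocalizationTable:
    """Replicate consensus: keep transcripts present in every replicate and
    average the localization indices (the per-replicate betas are averaged
    only for bookkeeping — indices are computed per replicate first)."""
    if not tables:
        raise ValueError("at least one table is required")
    if len(tables) == 1:
        return tables[0]
    ids = tables[0].transcript_ids
    for t in tables[1:]:
        ids = ids.intersection(t.transcript_ids)
    if ids.empty:
        raise QuantDataError("replicates share no transcripts")
    ids = ids.sort_values()
    li = np.mean([t.records["li"].reindex(ids).to_numpy(float) for t in tables], axis=0)
    naive = np.mean(
        [t.records["naive_li"].reindex(ids).to_numpy(float) for t in tables], axis=0
    )
    records = pd.DataFrame(
        {"li": li, "naive_li": naive, "label": classify(li, lower, upper)},
        index=pd.Index(ids, name="transcript_id"),
    )
    sample_id = "+".join(t.sample_id for t in tables)
    beta = float(np.mean([t.beta_used for t in tables]))
    return LocalizationTable(sample_id, beta, records)


def consistency_summary(
    tables: Mapping[str, LocalizationTable], threshold: float = 0.5
) -> pd.DataFrame:
    """Cross-condition localization consistency, binned by breadth of expression.

    For each transcript, count the conditions in which it appears (post-filter
    presence = expressed). Within each bin ``k`` report how many transcripts
    are cytosolic in all ``k`` conditions (``LI >= threshold`` everywhere) and
    nuclear in all (``LI <= threshold``). A transcript sitting exactly at the
    threshold in every condition satisfies both definitions and is counted in
    both tallies; the ``n_ties`` column reports that overlap explicitly.
    Undefined indices are excluded and tallied in ``n_undefined``.
    """
    if not tables:
        raise ValueError("at least one condition is required")
    li_by_tx: dict[str, list[float]] = {}
    n_undefined = 0
    for table in tables.values():
        for tx, li in table.records["li"].items():
            if np.isnan(li):
                n_undefined += 1
                continue
            li_by_tx.setdefault(tx, []).append(float(li))
    rows = []
    K = len(tables)
    for k in range(1, K + 1):
        in_bin = {tx: v for tx, v in li_by_tx.items() if len(v) == k}
        n = len(in_bin)
        cyto = sum(all(li >= threshold for li in v) for v in in_bin.values())
        nuc = sum(all(li <= threshold for li in v) for v in in_bin.values())
        ties = sum(all(li == threshold for li in v) for v in in_bin.values())
        rows.append(
            {
                "k": k,
                "n_expressed": n,
                "n_always_cytosolic": cyto,
                "n_always_nuclear": nuc,
                "n_ties": ties,
                "prop_always_cytosolic": cyto / n if n else np.nan,
                "prop_always_nuclear": nuc / n if n else np.nan,
                "n_undefined": n_undefined if k == 1 else 0,
            }
        )
    return pd.DataFrame(rows).set_index("k")


def strong_localizers(
    tables: Mapping[str, LocalizationTable],
    min_conditions: int = 5,
    cyto_cut: float = 0.9,
    nuc_cut: float = 0.3,
) -> tuple[set[str], set[str]]:
    """Transcripts with very strong, condition-invariant localization.

    Returns (strong cytosolic, strong nuclear): transcripts expressed in at
    least ``min_conditions`` conditions whose LI exceeds ``cyto_cut`` (resp.
    falls below ``nuc_cut``) in every condition where expressed.
    """
    if min_conditions < 1:
        raise ValueError("min_conditions must be >= 1")
    li_by_tx: dict[str, list[float]] = {}
    for table in tables.values():
        for tx, li in table.records["li"].items():
            if not np.isnan(li):
                li_by_tx.setdefault(tx, []).append(float(li))
    cyto = {
        tx for tx, v in li_by_tx.items()
        if len(v) >= min_conditions and all(li > cyto_cut for li in v)
    }
    nuc = {
        tx for tx, v in li_by_tx.items()
        if len(v) >= min_conditions and all(li < nuc_cut for li in v)
    }
    return cyto, nuc


def enrichment_ratio(
    flags_specific: Sequence[bool], flags_global: Sequence[bool]
) -> tuple[float, float]:
    """Enrichment of a feature in a localization-specific set of items.

    ``flags_global`` marks the feature (e.g. intron retention ratio > 0.5)
    over the full population of items; ``flags_specific`` marks it over the
    localization-specific subset. Returns the frequency ratio
    (specific / global) and the upper-tail hypergeometric p-value of drawing
    at least the observed number of flagged items when sampling the subset
    from the population. Multiple-testing (Bonferroni) correction across
    conditions is the caller's responsibility.
    """
    spec = np.asarray(flags_specific, bool)
    glob = np.asarray(flags_global, bool)
    if glob.size == 0:
        raise ValueError("global set must be non-empty")
    if spec.size == 0:
        raise ValueError("specific set is empty: enrichment undefined")
    if spec.size > glob.size or spec.sum() > glob.sum():
        raise ValueError("specific set must be a subset of the global set")
    k, n = int(spec.sum()), spec.size
    K, N = int(glob.sum()), glob.size
    freq_global = K / N
    if freq_global == 0:
        raise ValueError("no flagged items in the global set: ratio undefined")
    ratio = (k / n) / freq_global
    p_value = float(stats.hypergeom.sf(k - 1, N, K, n))
    return float(ratio), min(p_value, 1.0)


def bonferroni(p_values: Iterable[float], m: int | None = None) -> np.ndarray:
    """Bonferroni-corrected p-values, clipped at 1."""
    p = np.asarray(list(p_values), float)
    m = m or len(p)
    return np.minimum(p * m, 1.0)
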