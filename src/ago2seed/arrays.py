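"""Probe-level two-channel array handling.

Reads tab-delimited probe tables, applies QC flag filtering, normalizes
(75th-percentile scaling for single-channel miRNA arrays; rank-consistency
filtered LOWESS for two-color whole-genome arrays) and builds log2-ratio
expression matrices.

Conventions
-----------
* miRNA arrays are single-channel (Cy5 only); ratios are computed between
  arrays, pairing each treatment array with its replicate-matched sham array.
* Whole-genome arrays are two-color (Cy5 = treated RNA, Cy3 = control RNA);
  ratios are within-array Cy5/Cy3.
* Spots with a negative QC flag are discarded before any normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import NormalizationError, ProbeTableFormatError, ProbeValidationError

log = logging.getLogger(__name__)

PROBE_COLUMNS = ("probe_id", "feature_id", "cy5", "cy3", "flag")

Arm = Literal["mirna", "mrna_total", "mrna_ago2ip"]
Condition = Literal["iri", "sham"]


@dataclass
class ProbeRecord:
    """One spot on the array: identity, channel intensities and QC flag."""

    probe_id: str
    feature_id: str
    cy5: float
    cy3: float | None = None
    flag: int = 0


@dataclass
class ArraySample:
    """One hybridized array with its experimental metadata.

    ``probes`` is a DataFrame with columns ``probe_id, feature_id, cy5, cy3,
    flag``; ``cy3`` is NaN throughout for single-channel (miRNA) arrays.
    """

    sample_id: str
    arm: Arm
    condition: Condition
    probes: pd.DataFrame
    genotype: str | None = None
    timepoint: str | None = None
    replicate: int = 0

    @property
    def two_channel(self) -> bool:
        return self.probes["cy3"].notna().any()

    def with_probes(self, probes: pd.DataFrame) -> "ArraySample":
        return replace(self, probes=probes.reset_index(drop=True))


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of normalized log2 quantities.

    ``values`` is features-by-samples; ``metadata`` is indexed by sample id
    with columns such as genotype, timepoint, replicate, arm.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def select_samples(self, **criteria) -> "ExpressionMatrix":
        """Subset columns by metadata equality, e.g. genotype='wildtype'."""
        mask = pd.Series(True, index=self.metadata.index)
        for key, val in criteria.items():
            mask &= self.metadata[key] == val
        cols = self.metadata.index[mask]
        return ExpressionMatrix(self.values[cols], self.metadata.loc[cols])

    def dropna(self) -> "ExpressionMatrix":
        """Drop features that failed (non-finite) in any retained sample."""
        finite = np.isfinite(self.values).all(axis=1)
        dropped = self.values.index[~finite]
        if len(dropped):
            log.info("dropping %d features with non-finite values", len(dropped))
        return ExpressionMatrix(self.values.loc[finite], self.metadata)

    def to_tsv(self, values_path: str | Path, metadata_path: str | Path | None = None) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="feature_id")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, values_path: str | Path, metadata_path: str | Path | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="feature_id")
        meta = pd.DataFrame(index=values.columns)
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
        return cls(values, meta)


# ---------------------------------------------------------------------------
# Probe table I/O
# ---------------------------------------------------------------------------

def read_probe_table(path: str | Path, *, sample_id: str | None = None,
                     arm: Arm = "mirna", condition: Condition = "iri",
                     genotype: str | None = None, timepoint: str | None = None,
                     replicate: int = 0) -> ArraySample:
    """Parse one tab-delimited probe table into an :class:`ArraySample`.

    The dialect is a header line ``probe_id\tfeature_id\tcy5\tcy3\tflag``
    followed by one row per spot; ``cy3`` may be empty for single-channel
    arrays.  Malformed rows are reported with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "feature_id": str})
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ProbeTableFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}")
    df = df[list(PROBE_COLUMNS)]
    bad_feature = df.index[df["feature_id"].isna() | (df["feature_id"].str.len() == 0)]
    if len(bad_feature):
        lines = ", ".join(str(i + 2) for i in bad_feature[:10])
        raise ProbeValidationError(f"{path}: empty feature_id at line(s) {lines}")
    for chan in ("cy5", "cy3"):
        neg = df.index[df[chan].notna() & (df[chan] < 0)]
        if len(neg):
            lines = ", ".join(str(i + 2) for i in neg[:10])
            raise ProbeValidationError(
                f"{path}: negative {chan} intensity at line(s) {lines}")
    df["flag"] = df["flag"].astype(int)
    return ArraySample(sample_id=sample_id or path.stem, arm=arm,
                       condition=condition, probes=df.reset_index(drop=True),
                       genotype=genotype, timepoint=timepoint, replicate=replicate)


def write_probe_table(sample: ArraySample, path: str | Path) -> None:
    """Write a probe table in the canonical dialect (deterministic formatting)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PROBE_COLUMNS) + "\n")
        for row in sample.probes.itertuples(index=False):
            cy3 = "" if row.cy3 is None or (isinstance(row.cy3, float) and np.isnan(row.cy3)) \
                else f"{row.cy3:.6f}"
            fh.write(f"{row.probe_id}\t{row.feature_id}\t{row.cy5:.6f}\t{cy3}\t{int(row.flag)}\n")


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def filter_flags(sample: ArraySample) -> ArraySample:
    """Drop spots whose QC flag is negative; spots with flag >= 0 are kept."""
    keep = sample.probes["flag"] >= 0
    retained = int(keep.sum())
    log.info("%s: retained %d/%d spots after flag filter",
             sample.sample_id, retained, len(keep))
    if retained == 0:
        log.warning("%s: flag filter removed every spot", sample.sample_id)
    return sample.with_probes(sample.probes[keep])


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _sample_intensities(sample: ArraySample) -> np.ndarray:
    vals = sample.probes["cy5"].to_numpy(dtype=float)
    if sample.two_channel:
        vals = np.concatenate([vals, sample.probes["cy3"].to_numpy(dtype=float)])
    return vals[np.isfinite(vals)]


def percentile_scale_normalize(samples: Sequence[ArraySample], percentile: float = 0.75,
                               reference: float | None = None
                               ) -> tuple[list[ArraySample], list[float]]:
    """Between-array scaling that equalizes upper-quartile intensities.

    Each array's intensities are multiplied by a scalar chosen so that its
    ``percentile`` quantile equals a cohort reference; the reference defaults
    to the geometric mean of the per-array quantiles, but may be fixed (e.g.
    to a constant) via ``reference``.  Returns the scaled samples and the
    scale factors applied, in input order.
    """
    if not samples:
        raise ValueError("need at least one sample")
    quantiles = []
    for s in samples:
        vals = _sample_intensities(s)
        if vals.size == 0 or np.all(vals == 0):
            raise NormalizationError(
                f"{s.sample_id}: all-zero or empty intensities; cannot scale")
        quantiles.append(float(np.quantile(vals, percentile)))
    quantiles_arr = np.asarray(quantiles)
    if np.any(quantiles_arr <= 0):
        raise NormalizationError("non-positive percentile intensity in cohort")
    ref = float(np.exp(np.mean(np.log(quantiles_arr)))) if reference is None else float(reference)
    out, factors = [], []
    for s, q in zip(samples, quantiles):
        factor = ref / q
        probes = s.probes.copy()
        probes["cy5"] = probes["cy5"] * factor
        probes["cy3"] = probes["cy3"] * factor
        out.append(s.with_probes(probes))
        factors.append(factor)
    log.info("percentile scaling: reference %.4g, factors %s", ref,
             ", ".join(f"{f:.4g}" for f in factors))
    return out, factors


def _ordinal_ranks(values: np.ndarray, probe_ids: np.ndarray) -> np.ndarray:
    """Ordinal ranks with ties broken deterministically by probe id."""
    order = np.lexsort((probe_ids, values))
    ranks = np.empty(len(values), dtype=float)
    ranks[order] = np.arange(len(values), dtype=float)
    return ranks


def lowess_normalize(sample: ArraySample, span: float = 0.3,
                     rank_tolerance: float = 0.05,
                     edge_exclusion: float = 0.05) -> ArraySample:
    """Rank-consistency-filtered LOWESS normalization of a two-color array.

    M = log2(cy5/cy3) and A = mean log2 intensity are computed per spot; the
    LOWESS trend of M on A is fitted only on rank-consistent spots (those
    whose cy5 and cy3 ranks differ by at most ``rank_tolerance`` of the array
    size, i.e. spots unlikely to be differentially expressed) and subtracted
    from every spot's M.  Channels are reconstituted from the corrected M and
    the unchanged A.

    Spots in the extreme ``edge_exclusion`` tails of the intensity
    distribution are excluded from the fit set: at the rank extremes the
    consistency criterion is vacuous (the lowest spot stays lowest however
    strongly it is repressed), so a differentially expressed spot there
    would otherwise pull the local trend onto itself.  Corrections beyond
    the fit range are held constant at the boundary value.
    """
    if not sample.two_channel:
        raise NormalizationError(f"{sample.sample_id}: LOWESS requires two channels")
    probes = sample.probes.copy()
    cy5 = probes["cy5"].to_numpy(dtype=float)
    cy3 = probes["cy3"].to_numpy(dtype=float)
    if np.any(cy5 <= 0) or np.any(cy3 <= 0):
        raise NormalizationError(
            f"{sample.sample_id}: non-positive intensities; filter before LOWESS")
    m = np.log2(cy5) - np.log2(cy3)
    a = 0.5 * (np.log2(cy5) + np.log2(cy3))
    n = len(m)
    ids = probes["probe_id"].to_numpy()
    r5, r3 = _ordinal_ranks(cy5, ids), _ordinal_ranks(cy3, ids)
    rank_gap = np.abs(r5 - r3) / n
    central = (r5 + r3) / 2.0 / max(n - 1, 1)
    fit_mask = ((rank_gap <= rank_tolerance)
                & (central >= edge_exclusion)
                & (central <= 1.0 - edge_exclusion))
    if int(fit_mask.sum()) < 10:
        raise NormalizationError(
            f"{sample.sample_id}: only {int(fit_mask.sum())} rank-consistent spots; "
            "increase rank_tolerance")
    fitted = _sm_lowess(m[fit_mask], a[fit_mask], frac=span, return_sorted=True)
    # interpolate the trend at every spot's A; constant beyond the fit range
    trend = np.interp(a, fitted[:, 0], fitted[:, 1])
    m_corr = m - trend
    probes["cy5"] = np.exp2(a + m_corr / 2.0)
    probes["cy3"] = np.exp2(a - m_corr / 2.0)
    log.info("%s: LOWESS fit on %d/%d rank-consistent spots",
             sample.sample_id, int(fit_mask.sum()), n)
    return sample.with_probes(probes)


def collapse_duplicate_features(sample: ArraySample) -> ArraySample:
    """Collapse multiple probes per feature to their per-channel median.

    Applied after normalization and before ratio computation.
    """
    probes = sample.probes
    if probes["feature_id"].is_unique:
        return sample
    agg = (probes.groupby("feature_id", sort=True)
           .agg(cy5=("cy5", "median"), cy3=("cy3", "median"), flag=("flag", "max"))
           .reset_index())
    agg.insert(0, "probe_id", agg["feature_id"])
    return sample.with_probes(agg[list(PROBE_COLUMNS)])


# ---------------------------------------------------------------------------
# Log2 ratios
# ---------------------------------------------------------------------------

def compute_log2_ratio(treated: ArraySample, control: ArraySample | None = None
                       ) -> pd.Series:
    """Per-feature log2 ratio of treated over control intensities.

    With ``control=None`` the sample must be two-channel and the within-array
    Cy5/Cy3 ratio is returned.  Otherwise the treated and control samples are
    matched on feature id and the between-array Cy5 ratio is returned.
    Features with non-positive intensity are dropped and reported.
    """
    if control is None:
        if not treated.two_channel:
            raise ValueError("within-array ratio requires a two-channel sample")
        df = treated.probes.set_index("feature_id")
        num, den = df["cy5"], df["cy3"]
    else:
        num = treated.probes.set_index("feature_id")["cy5"]
        den = control.probes.set_index("feature_id")["cy5"]
        common = num.index.intersection(den.index)
        num, den = num.loc[common], den.loc[common]
    valid = (num > 0) & (den > 0)
    if (~valid).any():
        log.warning("dropping %d features with non-positive intensity from ratio",
                    int((~valid).sum()))
    ratio = np.log2(num[valid] / den[valid])
    ratio.name = treated.sample_id
    return ratio.sort_index()


def build_ratio_matrix(pairs: Iterable[tuple[ArraySample, ArraySample | None]]
                       ) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from (treated, control) pairs.

    Each pair contributes one column named after the treated sample; features
    missing in any column become NaN (use :meth:`ExpressionMatrix.dropna`).
    """
    columns, meta_rows = [], []
    for treated, control in pairs:
        columns.append(compute_log2_ratio(treated, control))
        meta_rows.append({"sample_id": treated.sample_id, "arm": treated.arm,
                          "genotype": treated.genotype, "timepoint": treated.timepoint,
                          "replicate": treated.replicate})
    values = pd.concat(columns, axis=1)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return ExpressionMatrix(values, meta)
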