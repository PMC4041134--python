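"""Two-library miRNA differential expression.

Counts are normalised to TPM (reads per million clean reads):

    TPM = count / total_clean_reads * 1e6

and compared between one control and one treatment library with the exact
two-library count test (Audic & Claverie).  Given a count ``x`` in a
library of depth ``N1``, the probability of observing ``y`` in a second
library of depth ``N2`` is

    p(y|x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1))

with lower/upper tail sums C(y<=ymin|x) and D(y>=ymax|x).  The default
p-value is the two-sided min(1, 2*min(C, D)).  A miRNA is called
differentially expressed when its fold change exceeds the cut-off (linear
1.5 by default) and p < 0.01; miRNAs below 10 TPM in both libraries are
filtered before testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

DEFAULT_PSEUDO_TPM = 0.01
DEFAULT_MIN_TPM = 10.0
DEFAULT_FC_CUTOFF = 1.5
DEFAULT_P_CUTOFF = 0.01


@dataclass(frozen=True)
class LibraryTotals:
    """Total clean reads per library (the TPM and test denominators)."""

    n1: int  # control
    n2: int  # treatment

    def __post_init__(self):
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")


def normalize_tpm(count: int, total: int) -> float:
    """count / total * 1e6; zero count maps to exactly 0."""
    if total <= 0:
        raise ValueError("total clean reads must be positive")
    if count < 0:
        raise ValueError("negative count")
    return count / total * 1e6


def log2_fold_change(
    tpm_treatment: float, tpm_control: float, pseudo: float = DEFAULT_PSEUDO_TPM
) -> float:
    """log2(treatment/control) with a small TPM floor guarding zeros.

    Positive = up-regulated in the treatment library.
    """
    return math.log2(max(tpm_treatment, pseudo) / max(tpm_control, pseudo))


def _log_pmf_block(x: int, ks: np.ndarray, log_r: float, log_1pr: float) -> np.ndarray:
    return (
        ks * log_r
        + gammaln(x + ks + 1)
        - gammaln(x + 1)
        - gammaln(ks + 1)
        - (x + ks + 1) * log_1pr
    )


def ac_pvalue(
    x: int, y: int, n1: int, n2: int, alternative: str = "two-sided"
) -> tuple[float, float, float]:
    """Exact two-library test; returns ``(C, D, p_value)``.

    C = P(Y <= y | x) and D = P(Y >= y | x) under the conditional law
    p(k|x).  Both tails are direct log-space sums (log-gamma terms combined
    with logsumexp); the upper tail is truncated once terms fall 20 orders
    of magnitude below the running maximum, so tiny tail probabilities keep
    full relative accuracy.  ``alternative`` is ``"two-sided"`` (default,
    min(1, 2*min(C, D))) or ``"one-sided"`` (min(C, D)).
    """
    for name, v in (("x", x), ("y", y)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    x, y = int(x), int(y)
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log1p(n2 / n1)

    ks_low = np.arange(0, y + 1)
    log_c = logsumexp(_log_pmf_block(x, ks_low, log_r, log_1pr))

    # upper tail: sum from y past the mode until terms are negligible
    r = n2 / n1
    mode = int(r * (x + 1) / 1.0)  # term ratio crosses 1 near r*(x+1)
    lo = y
    chunks = []
    max_term = -math.inf
    while True:
        hi = max(lo + 256, mode + 2)
        ks = np.arange(lo, hi)
        block = _log_pmf_block(x, ks, log_r, log_1pr)
        chunks.append(block)
        max_term = max(max_term, float(block.max()))
        if hi > mode and block[-1] < max_term - 46.2:  # ~1e-20 relative
            break
        lo = hi
    log_d = logsumexp(np.concatenate(chunks))

    c = min(1.0, math.exp(log_c))
    d = min(1.0, math.exp(log_d))
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(c, d))
    elif alternative == "one-sided":
        p = min(c, d)
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return c, d, p


def ac_tail_table(
    x: int, y_max: int, n1: int, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Both tails for every y in 0..y_max at fixed x (bulk use).

    Returns ``(C, D)`` arrays.  Tails are accumulated in log space
    (``logaddexp``), the upper tail from beyond the point where terms fall
    ~20 orders of magnitude below the largest, so relative accuracy is
    preserved for tiny tails.
    """
    if x < 0 or y_max < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log1p(n2 / n1)
    r = n2 / n1
    k_hi = y_max + 64
    # truncation must be relative to the SMALLEST reported tail, whose
    # leading term is p(y_max|x); remainder <= r * last term
    cut = 37.0 + math.log(max(r, 1.0))
    while True:
        ks = np.arange(0, k_hi + 1)
        logp = _log_pmf_block(x, ks, log_r, log_1pr)
        mode = int(min(r * (x + 1), k_hi))
        if k_hi > mode and logp[-1] < logp[y_max] - cut:
            break
        k_hi = 2 * k_hi + 64
    log_c = np.logaddexp.accumulate(logp)
    log_d = np.logaddexp.accumulate(logp[::-1])[::-1]
    return (
        np.minimum(np.exp(log_c[: y_max + 1]), 1.0),
        np.minimum(np.exp(log_d[: y_max + 1]), 1.0),
    )


def expression_table(
    counts: pd.DataFrame,
    totals: LibraryTotals,
    pseudo: float = DEFAULT_PSEUDO_TPM,
    alternative: str = "two-sided",
    with_bh: bool = True,
) -> pd.DataFrame:
    """Per-miRNA expression records.

    ``counts`` needs columns ``mirna_id``, ``x`` (control count) and ``y``
    (treatment count).  Adds TPMs, log2 fold change, both tails, the
    p-value and (optionally) a Benjamini-Hochberg column that is provided
    for downstream use but never used in DE calls.
    """
    df = counts.copy()
    df["tpm1"] = [normalize_tpm(v, totals.n1) for v in df["x"]]
    df["tpm2"] = [normalize_tpm(v, totals.n2) for v in df["y"]]
    df["log2fc"] = [
        log2_fold_change(t2, t1, pseudo) for t1, t2 in zip(df["tpm1"], df["tpm2"])
    ]
    tails = [
        ac_pvalue(xv, yv, totals.n1, totals.n2, alternative)
        for xv, yv in zip(df["x"], df["y"])
    ]
    df["p_low"] = [t[0] for t in tails]
    df["p_high"] = [t[1] for t in tails]
    df["p_value"] = [t[2] for t in tails]
    if with_bh:
        from statsmodels.stats.multitest import multipletests

        if len(df):
            df["bh_fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
        else:
            df["bh_fdr"] = []
    return df


def filter_low_expression(
    records: pd.DataFrame,
    threshold: float = DEFAULT_MIN_TPM,
    mode: str = "both",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into (retained, filtered) by the TPM floor.

    ``mode="both"`` (default) filters a miRNA only when it is below the
    threshold in both libraries; ``mode="either"`` filters when below in
    at least one.  Row counts are conserved.
    """
    if mode == "both":
        low = (records["tpm1"] < threshold) & (records["tpm2"] < threshold)
    elif mode == "either":
        low = (records["tpm1"] < threshold) | (records["tpm2"] < threshold)
    else:
        raise ValueError(f"unknown filter mode: {mode!r}")
    return records[~low].copy(), records[low].copy()


def call_de(
    log2fc: float,
    p_value: float,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    fc_scale: str = "linear",
) -> str:
    """DE call: ``up`` / ``down`` / ``ns``.

    ``fc_scale="linear"`` reads the cut-off as a linear ratio (1.5 means
    |log2fc| >= log2(1.5)); ``fc_scale="log2"`` reads it directly as a
    log2 threshold.
    """
    if fc_scale == "linear":
        lfc_cut = math.log2(fc_cutoff)
    elif fc_scale == "log2":
        lfc_cut = fc_cutoff
    else:
        raise ValueError(f"unknown fc_scale: {fc_scale!r}")
    if p_value < p_cutoff:
        if log2fc >= lfc_cut:
            return "up"
        if log2fc <= -lfc_cut:
            return "down"
    return "ns"


def differential_expression(
    counts: pd.DataFrame,
    totals: LibraryTotals,
    min_tpm: float = DEFAULT_MIN_TPM,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    fc_scale: str = "linear",
    filter_mode: str = "both",
    alternative: str = "two-sided",
    pseudo: float = DEFAULT_PSEUDO_TPM,
) -> pd.DataFrame:
    """Full DE pipeline: normalise, test, filter, call.

    Returns one row per input miRNA with ``call`` in
    {up, down, ns, filtered}.
    """
    df = expression_table(counts, totals, pseudo=pseudo, alternative=alternative)
    retained, filtered = filter_low_expression(df, threshold=min_tpm, mode=filter_mode)
    retained["call"] = [
        call_de(l, p, fc_cutoff, p_cutoff, fc_scale)
        for l, p in zip(retained["log2fc"], retained["p_value"])
    ]
    filtered["call"] = "filtered"
    out = pd.concat([retained, filtered], axis=0).loc[df.index]
    return out
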