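"""ddCt relative expression from qPCR Ct tables, and concordance with
sequencing calls.

Relative expression follows the ddCt algorithm with a reference gene
(e.g. actin) and the control condition as calibrator set to 1:

    dCt   = Ct_target - Ct_reference           (per replicate)
    ddCt  = mean dCt(treatment) - mean dCt(control)
    RE    = 2^(-ddCt)

Amplification efficiency is fixed at 2 (the ddCt assumption).  A
sequencing DE call is concordant with qPCR when the qPCR direction
(RE > 1 means up) agrees and, by default, the replicate dCt difference is
significant by a two-sample t-test at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("sample", "condition", "target", "ct_target", "ct_reference")
CONDITIONS = ("control", "treatment")


@dataclass
class RelativeExpression:
    """ddCt result for one target."""

    target: str
    ddct: float
    re_treatment: float
    re_control: float  # 1.0 by construction
    replicate_re: dict[str, list[float]]  # per-condition 2^-(dCt - mean control dCt)
    re_sd: dict[str, float]
    dct: dict[str, list[float]]


def _check_table(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    bad = df[df["ct_reference"].isna() | df["ct_target"].isna()]
    if len(bad):
        sample = bad.iloc[0]["sample"]
        raise ValueError(f"missing Ct value for sample {sample!r}")


def ddct_relative_expression(measurements: pd.DataFrame) -> RelativeExpression:
    """ddCt for one target's measurements (both conditions, >=1 replicate).

    The control condition is the calibrator: RE(control) = 1 exactly.
    Per-replicate REs (relative to the mean control dCt) and their SD per
    condition are returned alongside the point estimate.
    """
    _check_table(measurements)
    targets = measurements["target"].unique()
    if len(targets) != 1:
        raise ValueError(f"expected one target, got {list(targets)}")
    dct: dict[str, list[float]] = {}
    for cond in CONDITIONS:
        sub = measurements[measurements["condition"] == cond]
        if not len(sub):
            raise ValueError(f"no replicates for condition {cond!r}")
        dct[cond] = list(sub["ct_target"] - sub["ct_reference"])
    mean_ctrl = sum(dct["control"]) / len(dct["control"])
    mean_trt = sum(dct["treatment"]) / len(dct["treatment"])
    ddct = mean_trt - mean_ctrl
    rep_re = {
        cond: [2.0 ** -(v - mean_ctrl) for v in vals] for cond, vals in dct.items()
    }
    sd = {
        cond: (pd.Series(vals).std(ddof=1) if len(vals) > 1 else 0.0)
        for cond, vals in rep_re.items()
    }
    return RelativeExpression(
        target=str(targets[0]),
        ddct=ddct,
        re_treatment=2.0 ** -ddct,
        re_control=1.0,
        replicate_re=rep_re,
        re_sd={k: float(v) for k, v in sd.items()},
        dct=dct,
    )


def relative_expression_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """ddCt per target over a multi-target Ct table."""
    _check_table(ct_table)
    rows = []
    for target, sub in ct_table.groupby("target", sort=True):
        re = ddct_relative_expression(sub)
        rows.append((target, re.ddct, re.re_treatment, re.re_sd["treatment"]))
    return pd.DataFrame(rows, columns=["target", "ddct", "re_treatment", "re_sd"])


def concordance_rate(
    seq_calls: dict[str, str],
    ct_table: pd.DataFrame,
    alpha: float = 0.05,
    require_significance: bool = True,
) -> tuple[float, pd.DataFrame, list[str]]:
    """Fraction of sequencing DE calls confirmed by qPCR.

    ``seq_calls`` maps miRNA id -> ``"up"`` / ``"down"``.  A miRNA is
    concordant when sign(log2 RE) matches the call and (if
    ``require_significance``) the replicate dCts differ between conditions
    by a two-sample t-test at ``alpha``.  Ids present in only one input
    are excluded from the rate and returned as untested.  The rate is a
    percentage rounded half-up to one decimal and is invariant to input
    row order.
    """
    from decimal import Decimal, ROUND_HALF_UP

    _check_table(ct_table)
    ct_targets = set(ct_table["target"])
    untested = sorted(
        (set(seq_calls) - ct_targets) | (ct_targets - set(seq_calls))
    )
    rows = []
    for target in sorted(set(seq_calls) & ct_targets):
        call = seq_calls[target]
        re = ddct_relative_expression(ct_table[ct_table["target"] == target])
        qpcr_dir = "up" if re.re_treatment > 1.0 else "down"
        significant = True
        if require_significance:
            if min(len(re.dct["control"]), len(re.dct["treatment"])) < 2:
                significant = False
            else:
                _, p = stats.ttest_ind(re.dct["treatment"], re.dct["control"])
                significant = bool(p < alpha)
        concordant = (qpcr_dir == call) and significant
        rows.append(
            (target, call, qpcr_dir, re.re_treatment, significant, concordant)
        )
    verdicts = pd.DataFrame(
        rows,
        columns=["target", "seq_call", "qpcr_direction", "re_treatment", "significant", "concordant"],
    )
    if not len(verdicts):
        return 0.0, verdicts, untested
    n_conc = int(verdicts["concordant"].sum())
    rate = float(
        (Decimal(n_conc) * 100 / Decimal(len(verdicts))).quantize(
            Decimal("0.1"), ROUND_HALF_UP
        )
    )
    return rate, verdicts, untested


def format_rate(n_concordant: int, n_tested: int) -> float:
    """Concordance percentage to one decimal (half-up), e.g. 23/26 -> 88.5."""
    from decimal import Decimal, ROUND_HALF_UP

    if n_tested <= 0:
        raise ValueError("no tested miRNAs")
    return float(
        (Decimal(n_concordant) * 100 / Decimal(n_tested)).quantize(
            Decimal("0.1"), ROUND_HALF_UP
        )
    )
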