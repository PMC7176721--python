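"""Empirical-Bayes moderated two-group testing with adaptive FDR control.

Per comparison, the chain is: two-group summaries → raw-scale fold-change
gate (default 1.3) → empirical-Bayes variance moderation → moderated t-test
→ π0 estimation → adaptive Benjamini–Hochberg adjustment.  The moderated
test shrinks each protein's pooled variance s²_g toward a prior s0² with
prior degrees of freedom d0 estimated from the spread of log s²_g across
proteins, and refers the statistic to a Student t with d0 + d_g degrees of
freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import AnalysisConfig
from .preprocess import ComparisonFrame, Status


@dataclass
class ModerationFit:
    """Empirical-Bayes variance-prior hyperparameters.

    d0 is the prior degrees of freedom (np.inf when the observed spread of
    log-variances is no larger than expected from sampling noise alone) and
    s0_sq the prior variance toward which per-protein variances are shrunk.
    """

    d0: float
    s0_sq: float
    s_g_sq: np.ndarray
    d_g: float

    def __post_init__(self) -> None:
        # d0 = 0 is allowed as the no-moderation limit (ordinary pooled t);
        # the fitting routine itself always returns d0 > 0.
        if not self.d0 >= 0:
            raise ValueError("d0 must be non-negative")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def group_stats(frame: ComparisonFrame) -> pd.DataFrame:
    """Two-group summaries of the imputed TESTED block.

    Returns one row per tested protein with the group means, the log2 fold
    change (MBR+ minus control), the pooled within-group variance and its
    residual degrees of freedom d_g = n_plus + n_control − 2.
    """
    if frame.tested_values is None:
        raise ValueError("frame must be imputed before computing group stats")
    n1, n2 = frame.n_plus, frame.n_control
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two replicates per group for variances")
    block = frame.tested_values
    plus = block[:, :n1]
    ctl = block[:, n1:]
    mean_plus = plus.mean(axis=1)
    mean_ctl = ctl.mean(axis=1)
    ss = ((plus - mean_plus[:, None]) ** 2).sum(axis=1) + (
        (ctl - mean_ctl[:, None]) ** 2
    ).sum(axis=1)
    d_g = n1 + n2 - 2
    ids = [frame.protein_ids[i] for i in frame.tested_index]
    return pd.DataFrame(
        {
            "protein_id": ids,
            "mean_plus": mean_plus,
            "mean_control": mean_ctl,
            "log2fc": mean_plus - mean_ctl,
            "s_g_sq": ss / d_g,
            "d_g": d_g,
        }
    )


def fold_change_gate(log2fc: np.ndarray, config: AnalysisConfig) -> np.ndarray:
    """Boolean gate: True where |log2FC| reaches log2 of the raw threshold.

    The gate is magnitude-based — both directions are tested, matching the
    two-sided volcano display — and the enriched-direction requirement is
    applied later, when the enriched set is composed.
    """
    return np.abs(np.asarray(log2fc)) >= config.log2_fc_threshold - 1e-12


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = _trigamma(x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s_g_sq: np.ndarray, d_g: float) -> ModerationFit:
    """Estimate (d0, s0²) by moment-matching the log sample variances.

    Under the scaled-F sampling model, z_g = log s²_g has mean
    log s0² + digamma(d_g/2) − log(d_g/2) − digamma(d0/2) + log(d0/2) and
    excess variance trigamma(d0/2) beyond the sampling term trigamma(d_g/2);
    matching the first two moments of z_g and inverting the trigamma gives
    the prior degrees of freedom.  Zero variances (possible after imputation
    of constant rows) are excluded from the fit with a warning.
    """
    s2 = np.asarray(s_g_sq, dtype=float)
    if np.all(s2 <= 0):
        raise ValueError("all sample variances are zero; cannot fit a prior")
    if np.any(s2 <= 0):
        warnings.warn(
            f"excluding {int(np.sum(s2 <= 0))} zero variances from the prior fit",
            stacklevel=2,
        )
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise ValueError("need at least two positive variances to fit a prior")
    z = np.log(pos)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    ebar = float(e.mean())
    m = e.size
    evar = float(np.sum((e - ebar) ** 2) / (m - 1) - _trigamma(d_g / 2.0))
    if evar <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(ebar))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationFit(d0=d0, s0_sq=s0_sq, s_g_sq=s2, d_g=float(d_g))


def moderated_t(
    log2fc: np.ndarray,
    s_g_sq: np.ndarray,
    d_g: float,
    n_plus: int,
    n_control: int,
    fit: ModerationFit,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Moderated t statistics, total df and two-sided p-values.

    The posterior variance s̃² = (d0·s0² + d_g·s²_g)/(d0 + d_g) replaces the
    pooled variance of the ordinary two-sample t; the statistic gains d0
    degrees of freedom.  At d0 = 0 this is exactly the ordinary pooled t; at
    d0 = ∞ it is a z-test against s0².
    """
    fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s_g_sq, dtype=float)
    if np.isinf(fit.d0):
        s_tilde_sq = np.full_like(s2, fit.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (fit.d0 * fit.s0_sq + d_g * s2) / (fit.d0 + d_g)
        df_total = fit.d0 + d_g
    if np.any(s_tilde_sq <= 0):
        raise ValueError("degenerate zero posterior variance; cannot test")
    se = np.sqrt(s_tilde_sq * (1.0 / n_plus + 1.0 / n_control))
    t = fc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return t, float(df_total), p


def estimate_pi0(p: np.ndarray, method: str = "mean2x") -> float:
    """Estimate the proportion of true null hypotheses.

    ``"mean2x"`` is the robust mean-based estimator min(1, 2·mean p);
    ``"storey"`` is the λ = 0.5 tail estimator #{p > λ}/(m·(1−λ)), capped
    at 1.  Both return a value in (0, 1]; an all-significant input can drive
    the estimate toward 0, in which case it is floored at 1/m.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("cannot estimate pi0 from an empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "mean2x":
        pi0 = min(1.0, 2.0 * float(p.mean()))
    elif method == "storey":
        lam = 0.5
        pi0 = min(1.0, float(np.sum(p > lam)) / (p.size * (1.0 - lam)))
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    return max(pi0, 1.0 / p.size)


def adaptive_bh(p: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """π0-adaptive Benjamini–Hochberg step-up adjustment.

    p_adj(i) = min over j ≥ i in sorted order of min(1, π0·m·p(j)/j); at
    π0 = 1 this is exactly the standard Benjamini–Hochberg adjustment.
    Tied p-values share an adjusted value.
    """
    p = np.asarray(p, dtype=float)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = pi0 * m * ranked / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class ComparisonResult:
    """Per-protein outcome of one MBR+ vs control comparison.

    ``table`` has one row per protein entering the comparison with columns
    protein_id, status, log2fc, t_mod, df_total, p, p_adj, significant and
    significant_enriched; ``meta`` records the comparison label, replicate
    counts, the fitted hyperparameters and the π0 estimate.
    """

    control: object
    prep: object
    table: pd.DataFrame
    meta: dict

    @property
    def label(self) -> str:
        return self.meta["comparison"]

    def significant_ids(self, enriched_only: bool = False) -> set[str]:
        col = "significant_enriched" if enriched_only else "significant"
        return set(self.table.loc[self.table[col], "protein_id"])


def run_comparison(frame: ComparisonFrame, config: AnalysisConfig) -> ComparisonResult:
    """Run the full testing chain on one imputed comparison frame."""
    n = len(frame.protein_ids)
    table = pd.DataFrame(
        {
            "protein_id": frame.protein_ids,
            "status": [s.value for s in frame.status],
            "log2fc": np.full(n, np.nan),
            "t_mod": np.full(n, np.nan),
            "df_total": np.full(n, np.nan),
            "p": np.full(n, np.nan),
            "p_adj": np.full(n, np.nan),
            "significant": np.zeros(n, dtype=bool),
            "significant_enriched": np.zeros(n, dtype=bool),
        }
    )
    meta = {
        "comparison": frame.label,
        "control": frame.control.value,
        "prep": frame.prep.value,
        "n_plus": frame.n_plus,
        "n_control": frame.n_control,
        "pi0_method": config.pi0_method,
        "d0": None,
        "s0_sq": None,
        "pi0": None,
    }
    tested = frame.tested_index
    if tested.size == 0:
        return ComparisonResult(frame.control, frame.prep, table, meta)

    stats_df = group_stats(frame)
    table.loc[tested, "log2fc"] = stats_df["log2fc"].to_numpy()

    gate = fold_change_gate(stats_df["log2fc"].to_numpy(), config)
    fc_filtered = tested[~gate]
    table.loc[fc_filtered, "status"] = Status.FC_FILTERED.value
    gated = tested[gate]
    if gated.size < 2:
        warnings.warn(
            f"{frame.label}: fewer than two proteins pass the fold-change gate; "
            "statuses reported without tests",
            stacklevel=2,
        )
        return ComparisonResult(frame.control, frame.prep, table, meta)

    sub = stats_df.loc[gate.nonzero()[0]]
    d_g = float(sub["d_g"].iloc[0])
    fit = fit_variance_prior(sub["s_g_sq"].to_numpy(), d_g)
    t, df_total, p = moderated_t(
        sub["log2fc"].to_numpy(), sub["s_g_sq"].to_numpy(), d_g,
        frame.n_plus, frame.n_control, fit,
    )
    pi0 = estimate_pi0(p, config.pi0_method)
    p_adj = adaptive_bh(p, pi0)

    table.loc[gated, "t_mod"] = t
    table.loc[gated, "df_total"] = df_total
    table.loc[gated, "p"] = p
    table.loc[gated, "p_adj"] = p_adj
    sig = p_adj < config.fdr_level
    table.loc[gated, "significant"] = sig
    enr = sig & (sub["log2fc"].to_numpy() >= config.log2_fc_threshold - 1e-12)
    table.loc[gated, "significant_enriched"] = enr

    meta.update(
        d0=float(fit.d0), s0_sq=float(fit.s0_sq), pi0=float(pi0),
        n_tested=int(gated.size),
    )
    return ComparisonResult(frame.control, frame.prep, table, meta)
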