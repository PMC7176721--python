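"""Identification filters, normalization, presence/absence partition and
expectation–maximization imputation.

The processing chain mirrors standard label-free quantification practice:
decoy/contaminant/site-only rows and proteins with too few unique peptides
are removed; proteins with fewer than two quantified values in every
condition are dropped; intensities are log2-transformed and median-centered
within each fraction × prep condition.  For each MBR+ vs control comparison,
proteins quantified in one condition but never detected in the other are set
aside as present/absent calls, and the remaining missing values are imputed
under a multivariate-normal model over the sample columns fitted by EM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import linalg

from .design import Fraction, Prep, comparison_label
from .io import LOG2, RAW, AnalysisConfig, IntensityTable


class Status(str, Enum):
    """Per-protein outcome class within one comparison."""

    TESTED = "tested"
    FC_FILTERED = "fc_filtered"
    PRESENT_ABSENT_PLUS = "present_absent_plus"
    PRESENT_ABSENT_CONTROL = "present_absent_control"
    DISCARDED = "discarded"


# ---------------------------------------------------------------------------
# identification-level and quantification-level filters


def filter_identifications(
    table: IntensityTable, config: AnalysisConfig
) -> tuple[IntensityTable, dict[str, int]]:
    """Drop decoy, contaminant and site-only rows and low-evidence proteins.

    Returns the filtered table (row order preserved) and the number of rows
    removed per reason; a row matching several reasons is counted once per
    reason.
    """
    removed = {"reverse": 0, "contaminant": 0, "only_by_site": 0,
               "unique_peptides": 0}
    keep = np.ones(table.n_proteins, dtype=bool)
    for i, rec in enumerate(table.records):
        bad = False
        if rec.is_reverse:
            removed["reverse"] += 1
            bad = True
        if rec.is_contaminant:
            removed["contaminant"] += 1
            bad = True
        if rec.is_only_by_site:
            removed["only_by_site"] += 1
            bad = True
        if rec.unique_peptides < config.min_unique_peptides:
            removed["unique_peptides"] += 1
            bad = True
        keep[i] = not bad
    return table.subset_rows(np.flatnonzero(keep)), removed


def filter_min_quantified(
    table: IntensityTable, config: AnalysisConfig
) -> IntensityTable:
    """Keep proteins with enough quantified values in at least one condition.

    A protein survives when some fraction × prep condition holds at least
    ``min_quantified_per_condition`` observed values.  Taken literally, the
    dual reading ("in every condition") would leave no protein with an empty
    condition and the presence/absence partition downstream could never
    fire, so the at-least-one-condition reading is used.
    """
    k = config.min_quantified_per_condition
    if k == 0:
        return table.copy()
    best = np.zeros(table.n_proteins, dtype=int)
    for fraction, prep in table.conditions:
        cols = table.condition_columns(fraction, prep)
        if len(cols) < k:
            warnings.warn(
                f"condition ({fraction.value}, {prep.value}) has {len(cols)} "
                f"samples, fewer than min_quantified_per_condition={k}",
                stacklevel=2,
            )
        best = np.maximum(best, table.mask[:, cols].sum(axis=1))
    return table.subset_rows(np.flatnonzero(best >= k))


# ---------------------------------------------------------------------------
# scale transform and normalization


def log2_transform(table: IntensityTable) -> IntensityTable:
    """Replace observed raw intensities by their base-2 logarithm."""
    if table.scale != RAW:
        raise ValueError("table is already on the log2 scale")
    out = table.copy()
    observed = out.values[out.mask]
    if np.any(observed <= 0):
        raise ValueError("observed intensity <= 0; zeros must be masked as missing")
    out.values = np.where(out.mask, np.log2(np.where(out.mask, out.values, 1.0)), 0.0)
    out.scale = LOG2
    return out


def median_center(table: IntensityTable) -> IntensityTable:
    """Median-center each sample within its fraction × prep condition.

    Every sample column is shifted by a constant so that its median of
    observed values equals the mean of the per-sample medians of its
    condition; within-sample ordering and pairwise differences are
    preserved exactly, and the operation is idempotent.
    """
    if table.scale != LOG2:
        raise ValueError("median centering expects log2-scale values")
    out = table.copy()
    for fraction, prep in table.conditions:
        cols = table.condition_columns(fraction, prep)
        medians = np.empty(len(cols))
        for idx, j in enumerate(cols):
            observed = out.values[out.mask[:, j], j]
            if observed.size == 0:
                raise ValueError(
                    f"sample {table.design[j].sample_id!r} has no observed values"
                )
            medians[idx] = np.median(observed)
        target = medians.mean()
        for idx, j in enumerate(cols):
            out.values[:, j] += target - medians[idx]
    out.values = np.where(out.mask, out.values, 0.0)
    return out


# ---------------------------------------------------------------------------
# presence/absence partition


@dataclass
class ComparisonFrame:
    """One MBR+ vs control comparison after partitioning (and imputation).

    ``values``/``mask`` hold the log2 sub-matrix of every protein entering
    the comparison, with the ``n_plus`` MBR+ columns first and the
    ``n_control`` control columns last.  ``tested_values`` is filled by
    :func:`impute_frame` for the TESTED rows only and contains no missing
    values.
    """

    control: Fraction
    prep: Prep
    protein_ids: list[str]
    status: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    n_plus: int
    n_control: int
    tested_values: np.ndarray | None = None
    em_info: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return comparison_label(self.control, self.prep)

    @property
    def tested_index(self) -> np.ndarray:
        # note: numpy's broadcast `==` misbehaves against str-subclass enums,
        # so compare element-wise
        flags = [s is Status.TESTED for s in self.status]
        return np.flatnonzero(np.asarray(flags, dtype=bool))

    def status_counts(self) -> dict[str, int]:
        out = {s.value: 0 for s in Status}
        for s in self.status:
            out[s.value] += 1
        return out


def partition_presence_absence(
    table: IntensityTable,
    control: Fraction,
    prep: Prep,
    config: AnalysisConfig,
) -> ComparisonFrame:
    """Classify proteins of one comparison into tested / present-absent.

    A protein quantified in at least ``min_quantified_per_condition``
    replicates of one condition and never detected in the other is a
    presence/absence call; proteins with data on both sides are TESTED;
    proteins with no data on either side — or detected on only one side but
    below the quantification threshold — are DISCARDED for this comparison.
    """
    if table.scale != LOG2:
        raise ValueError("partition expects a log2-scale, normalized table")
    plus_cols = table.condition_columns(Fraction.MBR_PLUS, prep)
    ctl_cols = table.condition_columns(control, prep)
    if len(plus_cols) == 0 or len(ctl_cols) == 0:
        raise ValueError(f"design lacks samples for comparison vs {control.value} "
                         f"({prep.value})")
    cols = np.concatenate([plus_cols, ctl_cols])
    mask = table.mask[:, cols]
    values = np.where(mask, table.values[:, cols], 0.0)
    n_plus_obs = mask[:, : len(plus_cols)].sum(axis=1)
    n_ctl_obs = mask[:, len(plus_cols):].sum(axis=1)

    k = max(1, config.min_quantified_per_condition)
    status = np.empty(table.n_proteins, dtype=object)
    for i in range(table.n_proteins):
        if n_plus_obs[i] > 0 and n_ctl_obs[i] > 0:
            status[i] = Status.TESTED
        elif n_ctl_obs[i] == 0 and n_plus_obs[i] >= k:
            status[i] = Status.PRESENT_ABSENT_PLUS
        elif n_plus_obs[i] == 0 and n_ctl_obs[i] >= k:
            status[i] = Status.PRESENT_ABSENT_CONTROL
        else:
            status[i] = Status.DISCARDED
    return ComparisonFrame(
        control=control,
        prep=prep,
        protein_ids=table.protein_ids,
        status=status,
        values=values,
        mask=mask,
        n_plus=len(plus_cols),
        n_control=len(ctl_cols),
    )


# ---------------------------------------------------------------------------
# EM imputation under a multivariate normal over sample columns


@dataclass
class EMFit:
    """Converged multivariate-normal fit (proteins as observations)."""

    mean: np.ndarray
    cov: np.ndarray
    n_iter: int
    loglik: list[float]
    converged: bool


def _patterns(mask: np.ndarray):
    """Group row indices by missingness pattern."""
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(mask):
        groups.setdefault(tuple(row), []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}


def _safe_cholesky(sigma: np.ndarray):
    """Cholesky with automatic ridge escalation on singular covariance."""
    ridge = 1e-6 * float(np.mean(np.diag(sigma)))
    for attempt in range(4):
        try:
            return linalg.cho_factor(sigma, lower=True), sigma
        except linalg.LinAlgError:
            sigma = sigma + ridge * np.eye(sigma.shape[0])
            ridge *= 100
    raise linalg.LinAlgError("covariance remained singular after ridge escalation")


def impute_em(
    values: np.ndarray,
    mask: np.ndarray,
    *,
    seed: int | np.random.Generator | None = None,
    mode: str = "draw",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, EMFit]:
    """Impute missing cells under a multivariate normal fitted by EM.

    The model treats sample columns as coordinates of a multivariate normal
    and proteins as independent observations.  EM iterates conditional
    expectations of the missing coordinates given the observed ones until
    the observed-data log-likelihood changes by less than ``tol`` in
    relative terms.  Missing cells are then filled either by a single
    seeded draw from the conditional normal (``mode="draw"``) or by the
    conditional mean (``mode="mean"``); observed cells are returned
    bit-identically.
    """
    X = np.asarray(values, dtype=float)
    M = np.asarray(mask, dtype=bool)
    if X.shape != M.shape:
        raise ValueError("values and mask must share a shape")
    n, p = X.shape
    if np.any(M.sum(axis=1) == 0):
        raise ValueError("cannot impute rows with no observed values")
    if np.any(M.sum(axis=0) == 0):
        raise ValueError("cannot impute columns with no observed values")
    if mode not in ("draw", "mean"):
        raise ValueError(f"unknown imputation mode {mode!r}")

    out = X.copy()
    out[~M] = np.nan

    if M.all():
        mu = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, bias=True).reshape(p, p)
        return X.copy(), EMFit(mu, cov, 0, [], True)

    groups = _patterns(M)

    # Start from observed-column moments with zero cross terms.
    mu = np.array([X[M[:, j], j].mean() for j in range(p)])
    var = np.array([max(X[M[:, j], j].var(), 1e-8) for j in range(p)])
    sigma = np.diag(var)

    logliks: list[float] = []
    converged = False
    it = 0
    cond: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for it in range(1, max_iter + 1):
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        ll = 0.0
        cond.clear()
        for key, rows in groups.items():
            obs = np.flatnonzero(key)
            mis = np.flatnonzero(~np.asarray(key, dtype=bool))
            xo = X[np.ix_(rows, obs)]
            (c, low), soo = _safe_cholesky(sigma[np.ix_(obs, obs)])
            resid = xo - mu[obs]
            solved = linalg.cho_solve((c, low), resid.T)  # (|obs|, n_rows)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            quad = np.einsum("ij,ji->i", resid, solved)
            ll += -0.5 * (
                len(rows) * (len(obs) * np.log(2 * np.pi) + logdet) + quad.sum()
            )
            xhat = np.empty((len(rows), p))
            xhat[:, obs] = xo
            if mis.size:
                beta = linalg.cho_solve((c, low), sigma[np.ix_(obs, mis)])
                cmean = mu[mis] + resid @ beta
                ccov = sigma[np.ix_(mis, mis)] - sigma[np.ix_(mis, obs)] @ beta
                xhat[:, mis] = cmean
                t2[np.ix_(mis, mis)] += len(rows) * ccov
                cond[key] = (cmean, ccov)
            t1 += xhat.sum(axis=0)
            t2 += xhat.T @ xhat
        mu = t1 / n
        sigma = t2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        logliks.append(ll)
        if len(logliks) >= 2:
            prev = logliks[-2]
            if abs(ll - prev) <= tol * (1.0 + abs(prev)):
                converged = True
                break
    if not converged:
        raise RuntimeError(
            "EM did not converge within "
            f"{max_iter} iterations (last log-likelihood change "
            f"{logliks[-1] - logliks[-2]:.3g})"
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for key, rows in groups.items():
        mis = np.flatnonzero(~np.asarray(key, dtype=bool))
        if mis.size == 0:
            continue
        cmean, ccov = cond[key]
        if mode == "mean":
            fill = cmean
        else:
            try:
                chol = np.linalg.cholesky(ccov + 1e-12 * np.eye(len(mis)))
            except np.linalg.LinAlgError:
                chol = np.linalg.cholesky(
                    ccov + 1e-8 * np.mean(np.diag(ccov)) * np.eye(len(mis))
                )
            z = rng.standard_normal((len(rows), len(mis)))
            fill = cmean + z @ chol.T
        out[np.ix_(rows, mis)] = fill
    out[M] = X[M]
    return out, EMFit(mu, sigma, it, logliks, converged)


def impute_frame(
    frame: ComparisonFrame,
    *,
    seed: int | np.random.Generator | None = None,
    mode: str = "draw",
) -> ComparisonFrame:
    """Impute the TESTED block of a comparison frame in place and return it."""
    idx = frame.tested_index
    if idx.size == 0:
        frame.tested_values = np.empty((0, frame.values.shape[1]))
        return frame
    completed, fit = impute_em(
        frame.values[idx], frame.mask[idx], seed=seed, mode=mode
    )
    frame.tested_values = completed
    frame.em_info = {"n_iter": fit.n_iter, "converged": fit.converged,
                     "mode": mode}
    return frame
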