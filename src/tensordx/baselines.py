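"""Per-tissue comparison methods and batch-corrected naive integration.

These are the conventional alternatives to the tensor pipeline: a Welch t
test, a SAM-style permutation statistic, and an empirical-Bayes moderated t
(our own approximations of SAM and limma, not replications of those
packages), each run per tissue with time points and replicates pooled as
i.i.d. samples; plus a ComBat-style empirical-Bayes location/scale batch
adjustment that merges the tissues into one matrix so the same per-gene
tests can be run on the "integrated" data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .geo_io import ExpressionTensor

_VAR_FLOOR = 1e-12


@dataclass
class TissueMatrix:
    """Probe x sample matrix for one tissue with per-sample group labels."""

    values: np.ndarray
    probe_ids: list[str]
    treatment: np.ndarray        # int label per sample
    strain: np.ndarray
    tissue: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.treatment = np.asarray(self.treatment)
        self.strain = np.asarray(self.strain)
        if self.values.shape != (len(self.probe_ids), len(self.treatment)):
            raise ValueError("values shape does not match probe/sample labels")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def tissue_matrix_from_tensor(tensor: ExpressionTensor,
                              tissue: int | str) -> TissueMatrix:
    """Flatten one tissue slice to probe x sample, pooling time/replicate."""
    tissues = tensor.axis_labels.get("tissue", [])
    t = tissues.index(tissue) if isinstance(tissue, str) else int(tissue)
    x = tensor.values[..., t]                       # (p, J, K, M, S)
    p, nj, nk, nm, ns = x.shape
    values = x.reshape(p, -1)
    grid = np.stack(np.meshgrid(np.arange(nj), np.arange(nk), np.arange(nm),
                                np.arange(ns), indexing="ij"), axis=-1)
    flat = grid.reshape(-1, 4)
    name = tissues[t] if tissues else str(t)
    return TissueMatrix(values, list(tensor.probe_ids),
                        treatment=flat[:, 2], strain=flat[:, 3], tissue=name)


@dataclass
class BaselineResult:
    """Per-probe statistics and the selected set for one baseline method."""

    method: str
    table: pd.DataFrame           # probe_id, statistic, p_raw, p_adj, selected
    threshold: float
    flags: dict | None = None

    @property
    def selected_ids(self) -> set[str]:
        return set(self.table.loc[self.table["selected"], "probe_id"])

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())


def _two_groups(matrix: TissueMatrix) -> tuple[np.ndarray, np.ndarray]:
    levels = np.unique(matrix.treatment)
    if len(levels) != 2:
        raise ValueError(f"expected 2 treatment groups, got {len(levels)}")
    a = matrix.values[:, matrix.treatment == levels[0]]
    b = matrix.values[:, matrix.treatment == levels[1]]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each treatment group needs >= 2 samples")
    return a, b


def _finish(method: str, matrix: TissueMatrix, statistic: np.ndarray,
            p_raw: np.ndarray, threshold: float,
            flags: dict | None = None) -> BaselineResult:
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    table = pd.DataFrame({
        "probe_id": matrix.probe_ids,
        "statistic": statistic,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "selected": p_adj < threshold,
    })
    return BaselineResult(method, table, threshold, flags)


def ttest_select(matrix: TissueMatrix, threshold: float = 0.05) -> BaselineResult:
    """Per-probe two-sided Welch t test between treatment groups.

    Zero-variance probes are computed with a variance floor and flagged.
    """
    a, b = _two_groups(matrix)
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    floored = (va < _VAR_FLOOR) & (vb < _VAR_FLOOR)
    va = np.maximum(va, _VAR_FLOOR)
    vb = np.maximum(vb, _VAR_FLOOR)
    se2 = va / na + vb / nb
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p_raw = 2.0 * stats.t.sf(np.abs(t), df)
    return _finish("ttest", matrix, t, p_raw, threshold,
                   flags={"variance_floored": np.flatnonzero(floored).tolist()})


def _sam_statistic(values: np.ndarray, mask_a: np.ndarray,
                   mask_b: np.ndarray, s0: float | None = None
                   ) -> tuple[np.ndarray, float]:
    a, b = values[:, mask_a], values[:, mask_b]
    na, nb = a.shape[1], b.shape[1]
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) \
        / (na + nb - 2)
    s = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if s0 is None:
        s0 = float(np.median(s))
    d = (a.mean(axis=1) - b.mean(axis=1)) / (s + s0)
    return d, s0


def sam_like_select(matrix: TissueMatrix, threshold: float = 0.05,
                    n_permutations: int = 200, seed: int = 0) -> BaselineResult:
    """SAM-style regularized d statistic with a pooled permutation null.

    d_i = (mean difference) / (s_i + s0), s0 = median of the per-probe
    standard errors s_i; significance from label permutations pooled across
    probes.  All distinct label splits are enumerated exactly whenever their
    number does not exceed ``n_permutations``; otherwise ``n_permutations``
    splits are sampled with the mandatory seed.
    """
    if n_permutations < 50:
        raise ValueError("n_permutations must be >= 50; for small designs "
                         "exact enumeration of all label splits is used "
                         "automatically")
    levels = np.unique(matrix.treatment)
    if len(levels) != 2:
        raise ValueError(f"expected 2 treatment groups, got {len(levels)}")
    n = matrix.n_samples
    na = int((matrix.treatment == levels[0]).sum())
    if na < 2 or n - na < 2:
        raise ValueError("each treatment group needs >= 2 samples")

    mask_a = matrix.treatment == levels[0]
    d_obs, s0 = _sam_statistic(matrix.values, mask_a, ~mask_a)

    n_exact = comb(n, na)
    null_stats: list[np.ndarray] = []
    if n_exact <= n_permutations:
        for combo in combinations(range(n), na):
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            d_perm, _ = _sam_statistic(matrix.values, m, ~m, s0=s0)
            null_stats.append(np.abs(d_perm))
        exact = True
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            m = np.zeros(n, dtype=bool)
            m[rng.choice(n, size=na, replace=False)] = True
            d_perm, _ = _sam_statistic(matrix.values, m, ~m, s0=s0)
            null_stats.append(np.abs(d_perm))
        exact = False

    pooled = np.sort(np.concatenate(null_stats))
    n_null = pooled.size
    # P[|d*| >= |d_i|] over the pooled permutation null
    count_ge = n_null - np.searchsorted(pooled, np.abs(d_obs), side="left")
    if exact:
        p_raw = count_ge / n_null
    else:
        p_raw = (count_ge + 1.0) / (n_null + 1.0)
    return _finish("sam_like", matrix, d_obs, p_raw, threshold,
                   flags={"s0": s0, "exact_enumeration": exact,
                          "n_null": int(n_null)})


def moderated_t_select(matrix: TissueMatrix,
                       threshold: float = 0.05) -> BaselineResult:
    """Empirical-Bayes moderated t between treatment groups.

    Per-probe variances are shrunk toward a pooled prior fitted by matching
    the moments of the log sample variances to a scaled-F model
    (method-of-moments on the digamma/trigamma scale); the moderated t uses
    the posterior variance with df augmented by the prior df.
    """
    if len(matrix.probe_ids) < 3:
        raise ValueError("need >= 3 probes to estimate the variance prior")
    a, b = _two_groups(matrix)
    na, nb = a.shape[1], b.shape[1]
    d_resid = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) \
        / d_resid
    sp2 = np.maximum(sp2, _VAR_FLOOR)
    d0, s02 = _fit_variance_prior(sp2, d_resid)
    if np.isinf(d0):
        s2_post = np.full_like(sp2, s02)
    else:
        s2_post = (d0 * s02 + d_resid * sp2) / (d0 + d_resid)
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(
        s2_post * (1.0 / na + 1.0 / nb))
    df_total = d_resid + d0
    p_raw = 2.0 * stats.t.sf(np.abs(t), df_total)
    return _finish("moderated_t", matrix, t, p_raw, threshold,
                   flags={"prior_df": float(d0), "prior_var": float(s02)})


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimates (d0, s0^2) of the scaled inverse-chi-squared variance
    prior, from the empirical distribution of log sample variances."""
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s02 = np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s02)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def combat_adjust(matrices: list[TissueMatrix], eb: bool = True,
                  max_iter: int = 100, conv: float = 1e-4) -> TissueMatrix:
    """Merge per-tissue matrices with an empirical-Bayes location/scale
    batch adjustment (tissue = batch).

    Per probe the data are standardized with the batch-size-weighted grand
    mean and pooled variance; per-batch additive (gamma) and multiplicative
    (delta^2) effects are estimated and, when ``eb`` is True, shrunk toward
    normal / inverse-gamma batch-level priors by the standard iterative
    posterior-mean solution before being removed.  ``eb=False`` removes the
    raw batch location/scale exactly (no shrinkage).
    """
    if len(matrices) < 2:
        raise ValueError("need >= 2 batches")
    probes = [p for p in matrices[0].probe_ids
              if all(p in set(m.probe_ids) for m in matrices[1:])]
    if not probes:
        raise ValueError("empty probe intersection across batches")
    aligned = []
    for m in matrices:
        lookup = {p: i for i, p in enumerate(m.probe_ids)}
        rows = [lookup[p] for p in probes]
        if m.values.shape[1] <= 1:
            raise ValueError(f"batch {m.tissue!r} has <= 1 sample")
        aligned.append(m.values[rows])
    x = np.concatenate(aligned, axis=1)
    batch_sizes = [m.values.shape[1] for m in matrices]
    batch_of = np.repeat(np.arange(len(matrices)), batch_sizes)
    n_total = x.shape[1]

    batch_means = np.stack([x[:, batch_of == i].mean(axis=1)
                            for i in range(len(matrices))], axis=1)
    weights = np.array(batch_sizes) / n_total
    grand_mean = batch_means @ weights
    resid = x - batch_means[:, batch_of]
    var_pooled = (resid ** 2).sum(axis=1) / n_total
    var_pooled = np.maximum(var_pooled, _VAR_FLOOR)
    z = (x - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    z_adj = np.empty_like(z)
    gamma_star_all = []
    for i, ni in enumerate(batch_sizes):
        zi = z[:, batch_of == i]
        gamma_hat = zi.mean(axis=1)
        delta_hat = zi.var(axis=1, ddof=1)
        if eb:
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
            m_d = delta_hat.mean()
            s2_d = delta_hat.var(ddof=1)
            a_prior = (2.0 * s2_d + m_d ** 2) / s2_d if s2_d > 0 else np.inf
            b_prior = (m_d * s2_d + m_d ** 3) / s2_d if s2_d > 0 else m_d
            gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
            for _ in range(max_iter):
                g_new = (ni * tau2 * gamma_hat + delta_star * gamma_bar) \
                    / (ni * tau2 + delta_star)
                ssr = ((zi - g_new[:, None]) ** 2).sum(axis=1)
                if np.isinf(a_prior):
                    d_new = np.full_like(delta_star, m_d)
                else:
                    d_new = (0.5 * ssr + b_prior) / (ni / 2.0 + a_prior - 1.0)
                change = max(np.max(np.abs(g_new - gamma_star) /
                                    (np.abs(gamma_star) + 1e-12)),
                             np.max(np.abs(d_new - delta_star) / delta_star))
                gamma_star, delta_star = g_new, d_new
                if change < conv:
                    break
        else:
            gamma_star = gamma_hat
            delta_star = np.maximum(delta_hat, _VAR_FLOOR)
        z_adj[:, batch_of == i] = (zi - gamma_star[:, None]) \
            / np.sqrt(delta_star)[:, None]
        gamma_star_all.append(gamma_star)

    out = z_adj * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    combined = TissueMatrix(
        out, probes,
        treatment=np.concatenate([m.treatment for m in matrices]),
        strain=np.concatenate([m.strain for m in matrices]),
        tissue="combined")
    combined.batch = batch_of                      # type: ignore[attr-defined]
    combined.gamma_star = np.stack(gamma_star_all, axis=1)  # type: ignore[attr-defined]
    combined.var_pooled = var_pooled               # type: ignore[attr-defined]
    return combined


def recall_at_fdr(p_raw: np.ndarray, truth_flags: np.ndarray,
                  target_fdr: float) -> float:
    """Recall of the largest p-value-ranked prefix whose empirical FDR does
    not exceed ``target_fdr`` (used to compare methods at matched FDR)."""
    p_raw = np.asarray(p_raw, dtype=float)
    truth = np.asarray(truth_flags, dtype=bool)
    n_pos = truth.sum()
    if n_pos == 0:
        return float("nan")
    order = np.argsort(p_raw, kind="stable")
    hits = truth[order]
    tp = np.cumsum(hits)
    k = np.arange(1, len(p_raw) + 1)
    fdr = (k - tp) / k
    ok = np.flatnonzero(fdr <= target_fdr + 1e-12)
    if ok.size == 0:
        return 0.0
    return float(tp[ok[-1]] / n_pos)


def empirical_fdr(selected: np.ndarray, truth_flags: np.ndarray) -> float:
    sel = np.asarray(selected, dtype=bool)
    if sel.sum() == 0:
        return 0.0
    fp = (sel & ~np.asarray(truth_flags, dtype=bool)).sum()
    return float(fp / sel.sum())
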