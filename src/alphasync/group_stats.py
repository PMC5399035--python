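"""Edge-wise group statistics: permutation ANCOVA, FDR, post-hoc contrasts.

Group differences in connectivity are tested per edge with the F statistic
for the group factor in the linear model ``value ~ group + age`` (Type-II
sum of squares: group after age).  Significance comes from a permutation
null: group labels are reshuffled over subjects (ages travel with their
subjects, group sizes preserved) and the permutation p-value is

    p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)

Benjamini–Hochberg FDR at Q = 0.05 controls the edge family; surviving
edges get permutation-corrected Tukey-style pairwise contrasts on
age-adjusted group means (max-|q| null over the three group pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

GROUPS = ("HC", "SCD", "MCI")
DEFAULT_N_PERM = 10000
DEFAULT_Q = 0.05


@dataclass
class Design:
    """Per-subject covariate design for the group comparison."""

    subject_ids: list[str]
    groups: np.ndarray
    age: np.ndarray
    scores: pd.DataFrame | None = None
    hippocampal_volume: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, object).astype(str)
        self.age = np.asarray(self.age, float)
        if len(self.subject_ids) != len(self.groups) or len(self.groups) != len(self.age):
            raise ValueError("subject_ids, groups and age must align")
        if np.any(~np.isfinite(self.age)):
            raise ValueError("missing ages are not allowed")
        labels, counts = np.unique(self.groups, return_counts=True)
        if counts.min() < 2:
            raise ValueError("every group needs at least 2 subjects")
        self.group_labels = [g for g in GROUPS if g in labels] or sorted(labels)

    @property
    def n(self) -> int:
        return len(self.subject_ids)


def _design_matrices(groups: np.ndarray, age: np.ndarray,
                     group_labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Full (dummies + age + intercept) and reduced (age + intercept)."""
    n = len(age)
    dummies = np.column_stack([(groups == g).astype(float)
                               for g in group_labels[1:]])
    ones = np.ones((n, 1))
    x_full = np.column_stack([ones, dummies, age])
    x_red = np.column_stack([ones, age])
    return x_full, x_red


def _rss(x: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Residual sums of squares of ``values`` (n × E) on design ``x``."""
    q, _ = np.linalg.qr(x)
    proj = q.T @ values
    return np.einsum("ne,ne->e", values, values) - np.einsum("ke,ke->e", proj, proj)


def ancova_f(values: np.ndarray, design: Design) -> np.ndarray:
    """Group-factor F (Type II: group adjusted for age) per edge.

    ``values`` is (n_subjects,) or (n_subjects, n_edges).  Degenerate
    edges with zero residual variance in the full model return F = 0.
    """
    v = np.asarray(values, float)
    squeeze = v.ndim == 1
    v = v.reshape(design.n, -1)
    g = len(design.group_labels)
    if design.n <= g + 2:
        raise ValueError("need n > n_groups + 2 subjects")
    x_full, x_red = _design_matrices(design.groups, design.age,
                                     design.group_labels)
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("rank-deficient design (confounded group/age)")
    rss_f = _rss(x_full, v)
    rss_r = _rss(x_red, v)
    df1 = g - 1
    df2 = design.n - g - 1
    num = np.maximum(rss_r - rss_f, 0.0) / df1
    den = rss_f / df2
    f = np.where(den > np.finfo(float).eps * np.maximum(1.0, rss_r),
                 num / np.where(den == 0, 1.0, den), 0.0)
    return float(f[0]) if squeeze else f


def permutation_ancova(values: np.ndarray, design: Design,
                       n_perm: int = DEFAULT_N_PERM, seed: int = 0
                       ) -> pd.DataFrame:
    """Permutation p-values for the group factor, one per edge.

    Group labels are permuted over subjects (sizes preserved, ages kept
    with subjects); the permutation F distribution is shared machinery
    with the observed statistic.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    v = np.asarray(values, float).reshape(design.n, -1)
    f_obs = np.atleast_1d(ancova_f(v, design))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(v.shape[1])
    groups = design.groups.copy()
    for _ in range(n_perm):
        perm = rng.permutation(design.n)
        d = Design(design.subject_ids, groups[perm], design.age)
        f_perm = np.atleast_1d(ancova_f(v, d))
        exceed += f_perm >= f_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({"F": f_obs, "p_perm": p})


def fdr_bh(p_values: np.ndarray, q: float = DEFAULT_Q
           ) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up: reject p_(i) ≤ i·Q/m up to the largest
    such rank.  Returns (rejection mask, p threshold used; 0 if none)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = np.arange(1, m + 1) * q / m
    below = np.flatnonzero(ranked <= crit)
    mask = np.zeros(m, bool)
    if below.size == 0:
        return mask, 0.0
    k = below[-1]
    mask[order[:k + 1]] = True
    return mask, float(ranked[k])


def _adjusted_means_and_q(values: np.ndarray, design: Design
                          ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Age-adjusted group means and Tukey q per group pair, vectorised over
    edges.  q_ij = (m_i − m_j) / (s·sqrt(0.5·(1/n_i + 1/n_j)))."""
    v = values.reshape(design.n, -1)
    g = len(design.group_labels)
    x_full, _ = _design_matrices(design.groups, design.age, design.group_labels)
    beta, *_ = np.linalg.lstsq(x_full, v, rcond=None)
    mean_age = design.age.mean()
    # adjusted mean of group k at the grand mean age
    adj = np.empty((g, v.shape[1]))
    adj[0] = beta[0] + beta[-1] * mean_age
    for k in range(1, g):
        adj[k] = adj[0] + beta[k]
    resid = v - x_full @ beta
    df2 = design.n - g - 1
    s = np.sqrt(np.einsum("ne,ne->e", resid, resid) / df2)
    counts = {lab: np.sum(design.groups == lab) for lab in design.group_labels}
    pairs = [(a, b) for i, a in enumerate(design.group_labels)
             for b in design.group_labels[i + 1:]]
    qstat = np.empty((len(pairs), v.shape[1]))
    for idx, (a, b) in enumerate(pairs):
        ia, ib = design.group_labels.index(a), design.group_labels.index(b)
        se = s * np.sqrt(0.5 * (1.0 / counts[a] + 1.0 / counts[b]))
        se = np.where(se == 0, np.inf, se)
        qstat[idx] = (adj[ia] - adj[ib]) / se
    return adj, qstat, pairs


def tukey_pairwise_permuted(values: np.ndarray, design: Design,
                            edge_mask: np.ndarray | None = None,
                            n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Permutation-corrected pairwise contrasts for FDR-surviving edges.

    For each edge, the observed |q| of each group pair is referred to the
    permutation distribution of the maximum |q| over all pairs (family-wise
    correction within the edge).  Directions report the sign of the
    age-adjusted mean difference (first minus second group of the pair).
    """
    v = np.asarray(values, float).reshape(design.n, -1)
    n_edges = v.shape[1]
    if edge_mask is None:
        edge_mask = np.ones(n_edges, bool)
    sel = np.flatnonzero(edge_mask)
    if sel.size == 0:
        return pd.DataFrame(columns=["edge", "group_a", "group_b",
                                     "difference", "q", "p_corrected"])
    vs = v[:, sel]
    _, q_obs, pairs = _adjusted_means_and_q(vs, design)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(q_obs)
    groups = design.groups.copy()
    for _ in range(n_perm):
        perm = rng.permutation(design.n)
        d = Design(design.subject_ids, groups[perm], design.age)
        _, q_perm, _ = _adjusted_means_and_q(vs, d)
        qmax = np.abs(q_perm).max(axis=0, keepdims=True)
        exceed += qmax >= np.abs(q_obs)
    p_corr = (1.0 + exceed) / (1.0 + n_perm)
    adj, _, _ = _adjusted_means_and_q(vs, design)
    rows = []
    for e_idx, e in enumerate(sel):
        for p_idx, (a, b) in enumerate(pairs):
            ia, ib = design.group_labels.index(a), design.group_labels.index(b)
            rows.append({"edge": int(e), "group_a": a, "group_b": b,
                         "difference": adj[ia, e_idx] - adj[ib, e_idx],
                         "q": q_obs[p_idx, e_idx],
                         "p_corrected": p_corr[p_idx, e_idx]})
    return pd.DataFrame(rows)


def edge_stats_table(values: np.ndarray, design: Design, edge_names: list[str],
                     n_perm: int = DEFAULT_N_PERM, q: float = DEFAULT_Q,
                     seed: int = 0, n_perm_posthoc: int | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full edge-wise pipeline: permutation ANCOVA → BH-FDR → post-hoc.

    Returns (edge table with F/p/fdr_rejected, pairwise table for
    surviving edges)."""
    res = permutation_ancova(values, design, n_perm=n_perm, seed=seed)
    mask, thr = fdr_bh(res["p_perm"].to_numpy(), q=q)
    res.insert(0, "edge", edge_names)
    res["fdr_rejected"] = mask
    res.attrs["fdr_threshold"] = thr
    pairwise = tukey_pairwise_permuted(
        values, design, edge_mask=mask,
        n_perm=n_perm_posthoc or min(n_perm, 2000), seed=seed + 1)
    if not pairwise.empty:
        pairwise["edge"] = [edge_names[e] for e in pairwise["edge"]]
    return res, pairwise


def correlate_scores(edge_values: np.ndarray, edge_names: list[str],
                     scores: pd.DataFrame, q: float = DEFAULT_Q,
                     method: str = "pearson") -> pd.DataFrame:
    """Pearson correlation of every (edge, score) pair with joint BH-FDR.

    The FDR family is all tested pairs at once (conservative reading of a
    joint correction)."""
    if method != "pearson":
        raise ValueError("only Pearson correlation is supported")
    v = np.asarray(edge_values, float).reshape(len(scores), -1)
    rows = []
    for j, ename in enumerate(edge_names):
        col = v[:, j]
        for sname in scores.columns:
            s = scores[sname].to_numpy(float)
            ok = np.isfinite(col) & np.isfinite(s)
            if ok.sum() < 3:
                raise ValueError(f"fewer than 3 paired observations for "
                                 f"({ename}, {sname})")
            if np.std(col[ok]) == 0 or np.std(s[ok]) == 0:
                raise ValueError(f"zero-variance input for ({ename}, {sname})")
            r, p = sstats.pearsonr(col[ok], s[ok])
            rows.append({"edge": ename, "score": sname, "r": r, "p": p,
                         "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    out["fdr_rejected"], _ = fdr_bh(out["p"].to_numpy(), q=q)
    return out


def compare_scalar_ancova(scalar: np.ndarray, design: Design,
                          n_perm: int = DEFAULT_N_PERM, seed: int = 0
                          ) -> dict:
    """Single-variable group comparison (e.g. normalized hippocampal
    volume): permutation ANCOVA with age covariate plus permuted pairwise
    contrasts; no FDR (one family member)."""
    scalar = np.asarray(scalar, float).reshape(-1, 1)
    res = permutation_ancova(scalar, design, n_perm=n_perm, seed=seed)
    pairwise = tukey_pairwise_permuted(scalar, design, n_perm=min(n_perm, 2000),
                                       seed=seed + 1)
    return {"F": float(res["F"].iloc[0]), "p_perm": float(res["p_perm"].iloc[0]),
            "pairwise": pairwise}
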