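"""Module-level (resting-state-network) group statistics and
virtual-lesion vulnerability analysis.

All group tests are nonparametric: Wilcoxon signed-rank for paired
within-subject contrasts, Friedman across modules (module is a
within-subject factor), Nemenyi all-pairs post-hoc on mean ranks, and
Benjamini–Hochberg FDR across test families. Effect sizes for paired
contrasts use Cohen's d on subject-level differences (mean difference
over SD of differences), and inter-network connections with d < 0.2
(below a small effect) are masked.

The vulnerability analysis deletes nodes module-by-module (plus a
whole-graph random schedule), tracking percent change in global
efficiency; the mean pointwise slope of each averaged curve summarizes
how fast communication degrades under that attack.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, InputError
from .graphs import DirectedConnectome
from .metrics import CentralityTable, global_efficiency
from .partition import NetworkPartition

__all__ = [
    "rsn_counts",
    "inter_rsn_tests",
    "sender_receiver",
    "rsn_centrality_comparison",
    "friedman_nemenyi",
    "lesion_curve",
    "targeted_attack",
    "single_node_lesions",
    "bh_fdr",
    "paired_cohens_d",
]

MIN_SUBJECTS = 6  # smallest n with attainable signed-rank significance


def rsn_counts(g: DirectedConnectome, partition: NetworkPartition) -> pd.DataFrame:
    """Module × module directed edge counts; diagonal = within-module.

    Conservation: the matrix total equals the graph's edge count.
    """
    if partition.p != g.p:
        raise InputError("partition does not cover the graph's nodes")
    names = partition.module_names
    idx = {m: k for k, m in enumerate(names)}
    mod = [idx[lab] for lab in partition.labels]
    c = np.zeros((len(names), len(names)), dtype=int)
    for i, j in g.edges:
        c[mod[i], mod[j]] += 1
    return pd.DataFrame(c, index=names, columns=names)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_cohens_d(diff) -> float:
    """Mean of paired differences over their SD (ddof=1)."""
    d = np.asarray(diff, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        return np.inf if d.mean() > 0 else (-np.inf if d.mean() < 0 else 0.0)
    return float(d.mean() / sd)


def _signed_rank(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p; ties/zeros handled classically.

    Zero differences are discarded; exact distribution for n <= 25,
    normal approximation with continuity correction above. All-zero
    differences give p = 1 (no evidence either way).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    mode = "exact" if d.size <= 25 else "approx"
    return float(
        stats.wilcoxon(d, zero_method="wilcox", mode=mode, correction=True).pvalue
    )


def inter_rsn_tests(
    counts: list,
    alpha: float = 0.05,
    effect_size_mask: float = 0.2,
) -> pd.DataFrame:
    """Which module pairs are connected, and in which direction?

    ``counts`` is one module × module count DataFrame per subject (from
    :func:`rsn_counts`, identical module order). Per module a and target
    b ≠ a, the shared count C[a,b] + C[b,a] is signed-rank tested
    against a's out-of-module total divided by (N_M − 1) — the equal-
    spread null. FDR corrects across all directed tests; a pair is
    connected when either of its two tests survives and the paired
    effect size reaches ``effect_size_mask``. For connected pairs, the
    proportion C[a,b] / (C[a,b] + C[b,a]) is signed-rank tested against
    0.5 (FDR across pairs) to fix a preferred direction.

    Returns one row per unordered pair: connected flag, effect size,
    direction (source→target or None), mean preferred-direction
    proportion, and adjusted p-values.
    """
    if len(counts) < MIN_SUBJECTS:
        raise InputError(f"need at least {MIN_SUBJECTS} subjects, got {len(counts)}")
    names = list(counts[0].index)
    n_mod = len(names)
    arr = np.stack([c.to_numpy() for c in counts]).astype(float)  # subj × M × M

    # connectivity tests: one per ordered (a, b)
    rows = []
    for a in range(n_mod):
        off = arr[:, a, :].sum(axis=1) + arr[:, :, a].sum(axis=1) - 2 * arr[:, a, a]
        null_val = off / (n_mod - 1)
        for b in range(n_mod):
            if b == a:
                continue
            shared = arr[:, a, b] + arr[:, b, a]
            rows.append(
                {
                    "a": a,
                    "b": b,
                    "p_conn": _signed_rank(shared, null_val),
                    "d": paired_cohens_d(shared - null_val),
                }
            )
    conn = pd.DataFrame(rows)
    conn["p_conn_adj"] = bh_fdr(conn["p_conn"])

    out = []
    pair_rows = []
    for a in range(n_mod):
        for b in range(a + 1, n_mod):
            ra = conn[(conn.a == a) & (conn.b == b)].iloc[0]
            rb = conn[(conn.a == b) & (conn.b == a)].iloc[0]
            sig = min(ra.p_conn_adj, rb.p_conn_adj) < alpha
            d_eff = ra.d if ra.p_conn_adj <= rb.p_conn_adj else rb.d
            connected = bool(sig and d_eff >= effect_size_mask)
            shared = arr[:, a, b] + arr[:, b, a]
            with np.errstate(invalid="ignore"):
                prop = np.where(shared > 0, arr[:, a, b] / np.where(shared > 0, shared, 1), np.nan)
            valid = ~np.isnan(prop)
            pair_rows.append((connected, prop[valid]))
            out.append(
                {
                    "module_a": names[a],
                    "module_b": names[b],
                    "connected": connected,
                    "effect_size": float(d_eff),
                    "p_connected_adj": float(min(ra.p_conn_adj, rb.p_conn_adj)),
                    "mean_prop_a_to_b": float(np.nanmean(prop)) if valid.any() else np.nan,
                }
            )
    result = pd.DataFrame(out)

    # direction tests on connected pairs only
    p_dir = np.full(len(result), np.nan)
    for k, (connected, prop) in enumerate(pair_rows):
        if connected and prop.size >= MIN_SUBJECTS:
            p_dir[k] = _signed_rank(prop, np.full_like(prop, 0.5))
    tested = ~np.isnan(p_dir)
    p_dir_adj = np.full(len(result), np.nan)
    if tested.any():
        p_dir_adj[tested] = bh_fdr(p_dir[tested])
    result["p_direction_adj"] = p_dir_adj
    direction = []
    for k, row in result.iterrows():
        if row.connected and tested[k] and p_dir_adj[k] < alpha:
            direction.append(
                f"{row.module_a}->{row.module_b}"
                if row.mean_prop_a_to_b > 0.5
                else f"{row.module_b}->{row.module_a}"
            )
        else:
            direction.append(None)
    result["direction"] = direction
    return result


def sender_receiver(
    tables: list,
    partition: NetworkPartition,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each module as sender, receiver, or balanced.

    Per module, mean nodal outdegree vs indegree is compared across
    subjects (signed-rank, FDR over modules). Senders have outdegree
    significantly above indegree; receivers the reverse. Modules with
    no edges in any subject are reported balanced with a degenerate
    flag.
    """
    if len(tables) < MIN_SUBJECTS:
        raise InputError(f"need at least {MIN_SUBJECTS} subjects, got {len(tables)}")
    names = partition.module_names
    mean_in = np.zeros((len(tables), len(names)))
    mean_out = np.zeros((len(tables), len(names)))
    for s, tab in enumerate(tables):
        df = tab.nodes if isinstance(tab, CentralityTable) else tab
        for k, name in enumerate(names):
            members = partition.members(name)
            mean_in[s, k] = df["k_in"].to_numpy()[members].mean()
            mean_out[s, k] = df["k_out"].to_numpy()[members].mean()
    pvals = np.array(
        [_signed_rank(mean_out[:, k], mean_in[:, k]) for k in range(len(names))]
    )
    padj = bh_fdr(pvals)
    rows = []
    for k, name in enumerate(names):
        degenerate = bool(np.all(mean_in[:, k] == 0) and np.all(mean_out[:, k] == 0))
        if degenerate or padj[k] >= alpha:
            cls = "balanced"
        else:
            cls = "sender" if mean_out[:, k].mean() > mean_in[:, k].mean() else "receiver"
        rows.append(
            {
                "module": name,
                "mean_indegree": mean_in[:, k].mean(),
                "mean_outdegree": mean_out[:, k].mean(),
                "p_adj": padj[k],
                "classification": cls,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def friedman_nemenyi(data: np.ndarray, alpha: float = 0.05) -> dict:
    """Friedman test across columns with Nemenyi all-pairs post-hoc.

    ``data`` is subjects × conditions. The post-hoc compares mean ranks;
    the pairwise statistic |R_i − R_j| / sqrt(k(k+1)/(12 n)) is referred
    to the studentized-range distribution (times sqrt(2)) with infinite
    degrees of freedom.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    if k < 2:
        raise InputError("need at least 2 conditions")
    ranks = stats.rankdata(x, axis=1)
    if np.all(np.ptp(x, axis=1) == 0):
        # every subject fully tied: no evidence of condition differences
        f_stat, f_p = 0.0, 1.0
    else:
        try:
            fr = stats.friedmanchisquare(*[x[:, j] for j in range(k)])
            f_stat, f_p = float(fr.statistic), float(fr.pvalue)
        except ValueError as exc:
            raise DegenerateDataError(str(exc)) from exc
        if not np.isfinite(f_stat):
            raise DegenerateDataError("Friedman statistic undefined (degenerate ranks)")
    mean_ranks = ranks.mean(axis=0)
    posthoc = np.ones((k, k))
    if f_p < alpha:
        se = np.sqrt(k * (k + 1) / (12.0 * n))
        for i in range(k):
            for j in range(i + 1, k):
                q = abs(mean_ranks[i] - mean_ranks[j]) / se
                pv = float(stats.studentized_range.sf(q * np.sqrt(2), k, np.inf))
                posthoc[i, j] = posthoc[j, i] = min(1.0, pv)
    return {
        "statistic": f_stat,
        "p_value": f_p,
        "mean_ranks": mean_ranks,
        "posthoc_p": posthoc,
        "significant": f_p < alpha,
    }


def rsn_centrality_comparison(
    tables: list,
    partition: NetworkPartition,
    metrics=("k_in", "k_out", "k_total", "betweenness"),
    alpha: float = 0.05,
) -> dict:
    """Friedman + Nemenyi comparison of module-mean centralities.

    For each metric, module means per subject form the subjects ×
    modules design; returns one report per metric.
    """
    names = partition.module_names
    reports = {}
    for metric in metrics:
        design = np.zeros((len(tables), len(names)))
        for s, tab in enumerate(tables):
            df = tab.nodes if isinstance(tab, CentralityTable) else tab
            vals = df[metric].to_numpy()
            for k, name in enumerate(names):
                design[s, k] = vals[partition.members(name)].mean()
        rep = friedman_nemenyi(design, alpha=alpha)
        rep["modules"] = names
        reports[metric] = rep
    return reports


# ---------------------------------------------------------------------------
# Virtual lesions


def lesion_curve(g: DirectedConnectome, schedule) -> np.ndarray:
    """Percent change in global efficiency after each deletion.

    Returns length ``len(schedule) + 1`` starting at 0% (no deletions).
    """
    schedule = [int(v) for v in schedule]
    if len(set(schedule)) != len(schedule):
        raise InputError("deletion schedule contains duplicates")
    if any(not 0 <= v < g.p for v in schedule):
        raise InputError("schedule node outside graph")
    if g.p - len(schedule) < 2:
        raise InputError("schedule would leave fewer than 2 nodes")
    e0 = global_efficiency(g)
    if e0 == 0:
        raise DegenerateDataError("baseline efficiency is 0; percent change undefined")
    curve = [0.0]
    deleted: list = []
    for v in schedule:
        deleted.append(v)
        ek = global_efficiency(g.delete_nodes(deleted))
        curve.append(100.0 * (ek - e0) / e0)
    return np.asarray(curve)


def targeted_attack(
    g: DirectedConnectome,
    partition: NetworkPartition,
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Module-targeted plus random attack curves with slope summaries.

    Per module, ``n_reps`` random intra-module deletion orders are
    averaged into one loss-of-efficiency curve; a random schedule over
    the whole graph (length = largest module) is the control. Returns a
    tidy frame with one row per (schedule, step): columns schedule,
    step, pct_change, plus per-schedule mean pointwise slope.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    if partition.p != g.p:
        raise InputError("partition does not cover the graph's nodes")
    rng = np.random.default_rng(seed)
    names = partition.module_names
    rows = []
    max_size = max(len(partition.members(m)) for m in names)
    schedules = [(name, partition.members(name)) for name in names]
    schedules.append(("random", None))
    for name, members in schedules:
        if members is None:
            pool = list(range(g.p))
            size = min(max_size, g.p - 2)
        else:
            pool = members
            size = len(members)
        curves = np.zeros((n_reps, size + 1))
        for r in range(n_reps):
            order = list(rng.permutation(pool)[:size])
            curves[r] = lesion_curve(g, order)
        mean_curve = curves.mean(axis=0)
        slope = float(np.diff(mean_curve).mean()) if size else 0.0
        for step, pct in enumerate(mean_curve):
            rows.append(
                {
                    "schedule": name,
                    "step": step,
                    "pct_change": float(pct),
                    "mean_slope": slope,
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)


def single_node_lesions(g: DirectedConnectome) -> np.ndarray:
    """Change in global efficiency from deleting each node alone."""
    if g.p < 3:
        raise InputError("need at least 3 nodes")
    e0 = global_efficiency(g)
    return np.array(
        [global_efficiency(g.delete_nodes([v])) - e0 for v in range(g.p)]
    )
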