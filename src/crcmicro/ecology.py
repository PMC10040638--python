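"""Community-level statistics for the BP / tumor-stage comparison.

Alpha diversity (Shannon), Bray-Curtis dissimilarity, a permutation-based
multivariate ANOVA on distance matrices (perMANOVA, adonis2-style marginal
tests), canonical analysis of principal coordinates (CAP), average variation
degree (AVD) as a community-stability index, UpSet-style set-intersection
counts, specificity-occupancy (SPEC-OCCU) specialist screening, and
rank-based groupwise differential abundance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "shannon", "bray_curtis", "permanova", "pairwise_permanova",
    "cap_ordination", "avd", "upset_counts", "spec_occu",
    "differential_abundance", "PermanovaResult", "AvdResult", "CapResult",
]


# ---------------------------------------------------------------------------
# diversity & distance


def shannon(profile: pd.DataFrame) -> pd.Series:
    """Shannon diversity H = -sum p ln p per sample (natural log).

    ``profile`` holds per-sample relative abundances (rows sum to 1).
    """
    p = profile.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=profile.index, name="shannon")


def bray_curtis(profile: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|x-y| / sum(x+y), in [0,1]."""
    vals = profile.to_numpy(dtype=float)
    if (vals < 0).any():
        raise InputError("negative abundances in profile")
    zero = profile.index[vals.sum(axis=1) == 0]
    if len(zero) >= 2:
        raise InputError(
            f"Bray-Curtis undefined between all-zero samples: {list(zero)}"
        )
    condensed = pdist(vals, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in profile.index])


# ---------------------------------------------------------------------------
# perMANOVA


@dataclass
class PermanovaResult:
    """Distance-based multivariate ANOVA table.

    ``table`` has one row per term plus a residual row, with columns
    ``df``, ``ss``, ``r2``, ``f`` and ``p``.  ``by`` records whether term
    sums of squares are marginal (adonis2 ``by="margin"`` semantics) or
    sequential (additive).
    """

    table: pd.DataFrame
    n_permutations: int
    by: str


def _gower_centered(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for one term: numeric -> centred covariate, else dummies."""
    col = metadata[term]
    if col.dtype.kind in "iufc":
        x = (col - col.mean()).to_numpy(dtype=float)[:, None]
        return x
    levels = pd.unique(col)
    if len(levels) < 2:
        raise InputError(f"term {term!r} has a single level {levels[0]!r}")
    dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
    return dummies


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10
    q = q[:, keep]
    return q @ q.T


def _term_stats(g, designs, by):
    """Return per-term SS, df and F given the Gower matrix and term designs."""
    n = g.shape[0]
    ones = np.ones((n, 1))
    full = np.hstack([ones] + [d for d in designs.values()])
    h_full = _hat(full)
    ss_total = np.trace(g) - (ones.T @ g @ ones).item() / n
    ss_model = np.trace(h_full @ g @ h_full) - (ones.T @ g @ ones).item() / n
    ss_res = ss_total - ss_model
    df_full = np.linalg.matrix_rank(full) - 1
    df_res = n - 1 - df_full

    out = {}
    if by == "terms":
        prev = [ones]
        ss_prev = 0.0
        for name, d in designs.items():
            prev.append(d)
            x = np.hstack(prev)
            h = _hat(x)
            ss_here = np.trace(h @ g @ h) - (ones.T @ g @ ones).item() / n
            ss_t = ss_here - ss_prev
            ss_prev = ss_here
            df_t = d.shape[1]
            out[name] = (ss_t, df_t)
    else:  # marginal
        for name, d in designs.items():
            reduced = np.hstack([ones] + [v for k, v in designs.items() if k != name])
            h_red = _hat(reduced)
            ss_red = np.trace(h_red @ g @ h_red) - (ones.T @ g @ ones).item() / n
            ss_t = ss_model - ss_red
            df_t = df_full - (np.linalg.matrix_rank(reduced) - 1)
            out[name] = (ss_t, max(df_t, 1))
    fstats = {
        name: (ss_t / df_t) / (ss_res / df_res) if df_res > 0 and ss_res > 0 else np.nan
        for name, (ss_t, df_t) in out.items()
    }
    return out, fstats, ss_total, ss_res, df_res


def permanova(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    terms,
    n_perm: int | str = 999,
    seed=None,
    by: str = "margin",
) -> PermanovaResult:
    """perMANOVA: partition a distance matrix by metadata factors.

    Pseudo-F is computed from the Gower-centred inner-product matrix;
    significance by free permutation of sample labels.  ``by="margin"``
    tests each term after all others (adonis2 default here); ``by="terms"``
    gives sequential, additive sums of squares.  ``n_perm="exact"``
    enumerates all label permutations (only feasible for small n) and then
    ``p = #{F_perm >= F_obs} / n!`` including the identity; otherwise
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    if isinstance(terms, str):
        terms = [terms]
    if by not in ("margin", "terms"):
        raise InputError(f"unknown partition mode {by!r}")
    ids = list(dist.ids)
    idx_by_str = {str(k): k for k in metadata.index}
    missing = [i for i in ids if i not in idx_by_str]
    if missing:
        raise InputError(f"samples missing from metadata: {missing}")
    meta = metadata.loc[[idx_by_str[i] for i in ids]]
    for t in terms:
        if meta[t].isna().any():
            raise InputError(f"missing values in term {t!r}")
        col = meta[t]
        if col.dtype.kind not in "iufc":
            vc = col.value_counts()
            if (vc < 2).any():
                bad = vc.index[vc < 2][0]
                raise InputError(f"term {t!r} has singleton level {bad!r}")
    designs = {t: _design(meta, t) for t in terms}
    d = dist.data
    g = _gower_centered(d)

    ss_terms, f_obs, ss_total, ss_res, df_res = _term_stats(g, designs, by)

    n = len(ids)
    if n_perm == "exact":
        if n > 9:
            raise InputError("exact enumeration only supported for n <= 9")
        perms = list(itertools.permutations(range(n)))
        counts = {t: 0 for t in terms}
        for perm in perms:
            idx = np.array(perm)
            gp = g[np.ix_(idx, idx)]
            _, f_perm, *_ = _term_stats(gp, designs, by)
            for t in terms:
                if f_perm[t] >= f_obs[t] - 1e-12:
                    counts[t] += 1
        n_used = len(perms)
        pvals = {t: counts[t] / n_used for t in terms}
    else:
        rng = np.random.default_rng(seed)
        n_used = int(n_perm)
        counts = {t: 0 for t in terms}
        for _ in range(n_used):
            idx = rng.permutation(n)
            gp = g[np.ix_(idx, idx)]
            _, f_perm, *_ = _term_stats(gp, designs, by)
            for t in terms:
                if f_perm[t] >= f_obs[t] - 1e-12:
                    counts[t] += 1
        pvals = {t: (1 + counts[t]) / (1 + n_used) for t in terms}

    rows = []
    for t in terms:
        ss_t, df_t = ss_terms[t]
        rows.append(
            (t, df_t, ss_t, ss_t / ss_total if ss_total > 0 else np.nan,
             f_obs[t], pvals[t])
        )
    rows.append(("residual", df_res, ss_res,
                 ss_res / ss_total if ss_total > 0 else np.nan, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "ss", "r2", "f", "p"])
    table = table.set_index("term")
    return PermanovaResult(table=table, n_permutations=n_used, by=by)


def pairwise_permanova(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    group_col: str = "group",
    n_perm: int = 999,
    seed=None,
    correction: str = "BH",
) -> pd.DataFrame:
    """Run perMANOVA on every group pair; BH-adjust across pairs."""
    rng = np.random.default_rng(seed)
    idx_by_str = {str(k): k for k in metadata.index}
    groups = sorted(pd.unique(metadata[group_col]))
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        members = [i for i in dist.ids
                   if metadata.loc[idx_by_str[i], group_col] in (g1, g2)]
        sizes = metadata.loc[[idx_by_str[i] for i in members], group_col].value_counts()
        if len(sizes) < 2 or (sizes < 2).any():
            rows.append((g1, g2, np.nan, np.nan, np.nan))
            continue
        sub = dist.filter(members)
        res = permanova(sub, metadata, [group_col], n_perm=n_perm,
                        seed=rng.integers(2**31))
        rows.append((g1, g2, res.table.loc[group_col, "r2"],
                     res.table.loc[group_col, "f"], res.table.loc[group_col, "p"]))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "r2", "f", "p"])
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# CAP ordination


@dataclass
class CapResult:
    scores: pd.DataFrame       # samples x canonical axes
    n_pcoa_axes: int           # axes retained (positive eigenvalues)
    m_axes: int                # PCo axes fed to the discriminant step
    loo_success: float         # leave-one-out classification success rate


def cap_ordination(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    group_col: str = "group",
    m_axes: int | str = "auto",
    condition: str | None = None,
    max_axes: int = 20,
) -> CapResult:
    """Canonical analysis of principal coordinates.

    Principal-coordinate decomposition of the distance matrix (axes with
    non-positive eigenvalues dropped), optional residualization on a
    conditioning variable, then linear discriminant analysis of the group
    factor on the leading ``m`` axes.  ``m`` is chosen by maximizing
    leave-one-out classification success (ties -> fewest axes).  Scores are
    sign-canonicalized so they do not depend on sample input order.
    """
    ids = list(dist.ids)
    if len(ids) < 3:
        raise InputError("CAP needs at least 3 samples")
    # order-canonical PCoA: decompose with samples sorted by id
    order = np.argsort(ids)
    sorted_ids = [ids[i] for i in order]
    dsorted = dist.data[np.ix_(order, order)]
    ord_res = pcoa(DistanceMatrix(dsorted, ids=sorted_ids),
                   method="eigh", number_of_dimensions=0)
    eigvals = ord_res.eigvals.to_numpy()
    pos = eigvals > 1e-10
    axes = ord_res.samples.to_numpy()[:, pos]
    if axes.shape[1] == 0:
        raise InputError("distance matrix has no positive eigenvalues")
    # canonical sign: first non-zero coordinate (in sorted-id order) positive
    for j in range(axes.shape[1]):
        col = axes[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            axes[:, j] = -col

    meta = metadata.loc[[_match_id(metadata, i) for i in sorted_ids]]
    y = meta[group_col].to_numpy()
    if condition is not None:
        cond = _design(meta, condition)
        x = np.hstack([np.ones((len(sorted_ids), 1)), cond])
        h = _hat(x)
        axes = axes - h @ axes

    upper = min(max_axes, axes.shape[1], len(sorted_ids) - 2)
    if m_axes == "auto":
        best_m, best_acc = 1, -1.0
        for m in range(1, upper + 1):
            acc = _loo_accuracy(axes[:, :m], y)
            if acc > best_acc + 1e-12:
                best_m, best_acc = m, acc
        m = best_m
        loo = best_acc
    else:
        m = int(m_axes)
        loo = _loo_accuracy(axes[:, :m], y)

    lda = LinearDiscriminantAnalysis()
    scores = lda.fit_transform(axes[:, :m], y)
    for j in range(scores.shape[1]):
        col = scores[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            scores[:, j] = -col
    score_df = pd.DataFrame(
        scores, index=sorted_ids,
        columns=[f"CAP{j + 1}" for j in range(scores.shape[1])],
    ).loc[ids]
    return CapResult(scores=score_df, n_pcoa_axes=int(pos.sum()), m_axes=m,
                     loo_success=loo)


def _match_id(metadata: pd.DataFrame, sid: str):
    if sid in metadata.index:
        return sid
    # distance-matrix ids are strings; fall back to positional match
    as_str = metadata.index.astype(str)
    pos = np.nonzero(as_str == sid)[0]
    if len(pos) == 0:
        raise InputError(f"sample {sid!r} missing from metadata")
    return metadata.index[pos[0]]


def _loo_accuracy(x: np.ndarray, y: np.ndarray) -> float:
    hits = 0
    for train, test in LeaveOneOut().split(x):
        if len(np.unique(y[train])) < 2:
            continue
        lda = LinearDiscriminantAnalysis()
        try:
            lda.fit(x[train], y[train])
        except np.linalg.LinAlgError:
            continue
        hits += int(lda.predict(x[test])[0] == y[test][0])
    return hits / len(y)


# ---------------------------------------------------------------------------
# AVD community stability


@dataclass
class AvdResult:
    per_sample: pd.Series      # AVD value per sample
    summary: pd.DataFrame      # per-group mean, sd, n, letter, no_variation flag
    anova_f: float
    anova_p: float


def avd(profile: pd.DataFrame, metadata: pd.DataFrame,
        group_col: str = "group") -> AvdResult:
    """Average variation degree: per-sample mean |z| of taxon abundances.

    Within each group every taxon with positive within-group sd is
    standardized; a sample's AVD is the mean absolute z-score across those
    taxa.  Lower AVD means a more homogeneous (more stable) community.
    Groups whose taxa all have zero variance get AVD 0 and a
    ``no_variation`` flag.  Group differences are tested by one-way ANOVA
    with Tukey-HSD compact letters at alpha = 0.05.
    """
    meta = metadata.loc[profile.index]
    values = {}
    flags = {}
    for g, sub in profile.groupby(meta[group_col]):
        if len(sub) < 2:
            raise InputError(f"group {g!r} has fewer than 2 samples")
        x = sub.to_numpy(dtype=float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        varying = sd > 0
        if not varying.any():
            for s in sub.index:
                values[s] = 0.0
            flags[g] = True
            continue
        z = np.abs((x[:, varying] - mu[varying]) / sd[varying])
        per = z.mean(axis=1)
        for s, v in zip(sub.index, per):
            values[s] = float(v)
        flags[g] = False
    per_sample = pd.Series(values, name="avd").loc[profile.index]

    groups = sorted(pd.unique(meta[group_col]))
    arrays = [per_sample[meta[group_col] == g].to_numpy() for g in groups]
    if len(groups) > 1 and all(len(a) > 1 for a in arrays):
        f, p = stats.f_oneway(*arrays)
    else:
        f, p = np.nan, np.nan
    letters = _tukey_letters(per_sample, meta[group_col], groups)
    summary = pd.DataFrame(
        {
            "mean": [a.mean() for a in arrays],
            "sd": [a.std(ddof=1) for a in arrays],
            "n": [len(a) for a in arrays],
            "letters": [letters[g] for g in groups],
            "no_variation": [flags[g] for g in groups],
        },
        index=pd.Index(groups, name=group_col),
    )
    return AvdResult(per_sample=per_sample, summary=summary,
                     anova_f=float(f), anova_p=float(p))


def _tukey_letters(values: pd.Series, groups: pd.Series, order) -> dict:
    """Compact letter display from Tukey-HSD pairwise tests at alpha=0.05."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(order) < 2:
        return {g: "a" for g in order}
    try:
        res = pairwise_tukeyhsd(values.to_numpy(), groups.to_numpy(), alpha=0.05)
    except Exception:
        return {g: "a" for g in order}
    sig = {}
    for (g1, g2), reject in zip(
        itertools.combinations(res.groupsunique, 2), res.reject
    ):
        sig[frozenset((g1, g2))] = bool(reject)
    means = values.groupby(groups).mean().reindex(order).sort_values(ascending=False)
    ranked = list(means.index)
    letter_sets: list[set] = []
    for g in ranked:
        placed = False
        for s in letter_sets:
            if all(not sig.get(frozenset((g, h)), False) for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # drop letter sets fully contained in another
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in order}
    for li, s in enumerate(letter_sets):
        for g in ranked:
            if g in s:
                out[g] += alphabet[li % len(alphabet)]
    return out


# ---------------------------------------------------------------------------
# UpSet intersections


def upset_counts(counts: pd.DataFrame, metadata: pd.DataFrame,
                 group_col: str = "group") -> pd.DataFrame:
    """Count taxa by their group-presence pattern (UpSet-plot table).

    A taxon is present in a group if nonzero in at least one of its samples.
    Every taxon present anywhere lands in exactly one of the 2^k - 1
    patterns; pattern counts sum to the number of nonzero taxa.
    """
    meta = metadata.loc[counts.index]
    groups = sorted(pd.unique(meta[group_col]))
    presence = pd.DataFrame(
        {g: (counts.loc[meta[group_col] == g] > 0).any(axis=0) for g in groups}
    )
    nonzero = presence.any(axis=1)
    presence = presence.loc[nonzero]
    patterns = presence.apply(lambda row: "&".join(g for g in groups if row[g]),
                              axis=1)
    table = patterns.value_counts().rename_axis("pattern").to_frame("n_taxa")
    table["degree"] = [p.count("&") + 1 for p in table.index]
    return table.sort_values(["degree", "n_taxa"], ascending=[True, False])


# ---------------------------------------------------------------------------
# SPEC-OCCU


def spec_occu(counts: pd.DataFrame, metadata: pd.DataFrame,
              group_col: str = "group", top_n: int = 500) -> pd.DataFrame:
    """Specificity-occupancy records for each group's most abundant taxa.

    Per group the ``top_n`` taxa by within-group mean relative abundance are
    kept.  Specificity of taxon i in group g is its group-mean relative
    abundance normalized across groups (so specificities sum to 1 over
    groups); occupancy is the fraction of the group's samples where the
    taxon is present.  Specialists satisfy specificity >= 0.5 and
    occupancy >= 0.5.
    """
    if top_n < 1:
        raise InputError("top_n must be >= 1")
    from .prep import to_relative

    rel = to_relative(counts)
    meta = metadata.loc[rel.index]
    groups = sorted(pd.unique(meta[group_col]))
    means = pd.DataFrame(
        {g: rel.loc[meta[group_col] == g].mean(axis=0) for g in groups}
    )
    denom = means.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        specificity = means.div(denom, axis=0).fillna(0.0)
    rows = []
    for g in groups:
        top = means[g].nlargest(min(top_n, means.shape[0])).index
        sub = rel.loc[meta[group_col] == g, top]
        occupancy = (sub > 0).mean(axis=0)
        for t in top:
            s = float(specificity.loc[t, g])
            o = float(occupancy[t])
            rows.append((t, g, s, o, s >= 0.5 and o >= 0.5))
    return pd.DataFrame(
        rows, columns=["taxon", "group", "specificity", "occupancy", "specialist"]
    )


# ---------------------------------------------------------------------------
# differential abundance


def differential_abundance(
    profile: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "group",
    method: str = "kruskal",
    correction: str = "BH",
) -> pd.DataFrame:
    """Per-taxon rank-based group test (Kruskal-Wallis) with BH correction.

    Constant taxa get p = 1 and a ``constant`` flag.  For two-group
    contrasts ``direction`` is the sign of the median difference
    (second group minus first, groups sorted).
    """
    if method != "kruskal":
        raise InputError(f"unsupported method {method!r}")
    meta = metadata.loc[profile.index]
    groups = sorted(pd.unique(meta[group_col]))
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    masks = [meta[group_col] == g for g in groups]
    rows = []
    for t in profile.columns:
        vals = [profile.loc[m, t].to_numpy(dtype=float) for m in masks]
        flat = np.concatenate(vals)
        if np.all(flat == flat[0]):
            rows.append((t, np.nan, 1.0, np.nan, True))
            continue
        stat, p = stats.kruskal(*vals)
        direction = np.nan
        if len(groups) == 2:
            direction = float(np.sign(np.median(vals[1]) - np.median(vals[0])))
        rows.append((t, stat, p, direction, False))
    out = pd.DataFrame(
        rows, columns=["taxon", "statistic", "p", "direction", "constant"]
    ).set_index("taxon")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
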