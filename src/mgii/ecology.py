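"""Community-ecology statistics on the read-recruitment RPKM matrix.

Given genome x sample RPKM from the high-recruitment samples, this module

* computes Bray-Curtis dissimilarities along either axis,
* builds average-linkage (UPGMA) dendrograms and cuts them at fixed
  dissimilarity heights (taxa at 0.8, samples at 0.7) to find *ecological
  clusters* — taxon/sample blocks with elevated RPKM,
* ordains samples against environmental gradients with canonical
  correspondence analysis (CCA),
* tests group structure with one-way PERMANOVA (pseudo-F, permutation p,
  default 9999 permutations) plus pairwise tests with Bonferroni adjustment
  and Benjamini-Hochberg FDR across related variables,
* bins environmental measurements into the fixed intervals used for the
  PERMANOVA groupings (with an explicit below-detection-limit category), and
* compares genome properties between groups with Welch's unequal-variance
  two-sided t-test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

DEFAULT_TAXON_CUT = 0.8
DEFAULT_SAMPLE_CUT = 0.7
DEFAULT_ELEVATION_MIN = 4.0
DEFAULT_N_PERM = 9999

#: sentinel for below-detection-limit measurements, distinct from missing
BDL = "BDL"


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with labels."""

    data: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("distance matrix must have a zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.data[i, j]


@dataclass
class Dendrogram:
    """Agglomeration result: ``merges`` is a list of (left, right, height,
    members) tuples where left/right index earlier merges or, if negative,
    leaves (-i-1 = leaf i); ``members`` is the sorted tuple of leaf labels of
    the merged cluster."""

    leaves: list[str]
    merges: list[tuple[int, int, float, tuple[str, ...]]]

    @property
    def root_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def cut(self, height: float) -> list[set[str]]:
        """Maximal subtrees whose merge heights are all < height."""
        parent = {lab: lab for lab in self.leaves}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for left, right, h, members in self.merges:
            if h < height:
                reps = {find(m) for m in members}
                anchor = min(reps)
                for r in reps:
                    parent[r] = anchor
        groups: dict[str, set[str]] = {}
        for lab in self.leaves:
            groups.setdefault(find(lab), set()).add(lab)
        return [groups[k] for k in sorted(groups)]

    def to_newick(self) -> str:
        if not self.merges:
            return f"({','.join(self.leaves)});"
        names: dict[int, str] = {}
        heights: dict[int, float] = {-i - 1: 0.0 for i in range(len(self.leaves))}
        for i, lab in enumerate(self.leaves):
            names[-i - 1] = lab
        for idx, (l, r, h, _members) in enumerate(self.merges):
            bl_l = h - heights[l]
            bl_r = h - heights[r]
            names[idx] = f"({names[l]}:{bl_l:.6g},{names[r]}:{bl_r:.6g})"
            heights[idx] = h
        return names[len(self.merges) - 1] + ";"


@dataclass
class EcologicalCluster:
    label: str
    taxa: set[str]
    samples: set[str]
    elevation: float  # block median RPKM / global nonzero median


@dataclass
class PermanovaResult:
    pseudo_f: float
    p: float
    n_permutations: int
    groups: list[str]
    seed: int | None = None


def bray_curtis(matrix: pd.DataFrame, axis: str = "taxa") -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y).

    ``axis='taxa'`` compares rows, ``axis='samples'`` compares columns.  A
    pair of all-zero vectors is undefined under the formula; it is reported
    as 0 with a warning (identical emptiness).
    """
    if (matrix.values < 0).any():
        raise ValueError("abundance matrix must be non-negative")
    if axis == "samples":
        matrix = matrix.T
    elif axis != "taxa":
        raise ValueError("axis must be 'taxa' or 'samples'")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 items to compare")
    with np.errstate(invalid="ignore", divide="ignore"):
        condensed = pdist(matrix.values, metric="braycurtis")
    if np.isnan(condensed).any():
        logger.warning("all-zero vector pair(s); defining their distance as 0")
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(squareform(condensed), [str(i) for i in matrix.index])


def average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration with a deterministic tie rule.

    The inter-cluster distance is the unweighted mean of all member pairwise
    distances from the original matrix; ties on distance are broken by the
    lexicographically smallest (min-leaf-label, min-leaf-label) pair, so the
    result is invariant to input ordering.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    labels = dist.labels
    d = dist.data
    idx_of = {lab: i for i, lab in enumerate(labels)}
    # active clusters: node id -> sorted tuple of leaf labels
    active: dict[int, tuple[str, ...]] = {-i - 1: (labels[i],) for i in range(n)}

    def cluster_dist(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        ia = [idx_of[x] for x in a]
        ib = [idx_of[x] for x in b]
        return float(d[np.ix_(ia, ib)].mean())

    merges: list[tuple[int, int, float, tuple[str, ...]]] = []
    while len(active) > 1:
        best = None
        for u in sorted(active, key=lambda k: active[k][0]):
            for v in sorted(active, key=lambda k: active[k][0]):
                if active[u][0] >= active[v][0]:
                    continue
                dd = cluster_dist(active[u], active[v])
                key = (dd, active[u][0], active[v][0])
                if best is None or key < best[0]:
                    best = (key, u, v)
        (dd, _, _), u, v = best
        members = tuple(sorted(active[u] + active[v]))
        merges.append((u, v, dd, members))
        del active[u], active[v]
        active[len(merges) - 1] = members
    return Dendrogram(leaves=list(labels), merges=merges)


def cut_dendrogram(dend: Dendrogram, height: float) -> list[set[str]]:
    if height < 0:
        raise ValueError("cut height must be non-negative")
    return dend.cut(height)


def ecological_clusters(rpkm: pd.DataFrame,
                        taxon_cut: float = DEFAULT_TAXON_CUT,
                        sample_cut: float = DEFAULT_SAMPLE_CUT,
                        elevation_min: float = DEFAULT_ELEVATION_MIN) -> list[EcologicalCluster]:
    """Taxon/sample blocks with elevated RPKM.

    Both axes are clustered (Bray-Curtis + UPGMA) and cut — taxa below 0.8,
    samples below 0.7 dissimilarity.  Every (taxon clade x sample clade)
    block is a candidate; blocks whose median RPKM is at least
    ``elevation_min`` times the global median of nonzero RPKM are kept and
    labeled A, B, ... in descending elevation.
    """
    rpkm = rpkm.copy()
    rpkm.index = rpkm.index.map(str)
    rpkm.columns = rpkm.columns.map(str)
    values = rpkm.values
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return []
    global_median = float(np.median(nonzero))
    taxon_groups = cut_dendrogram(average_linkage(bray_curtis(rpkm, "taxa")), taxon_cut)
    sample_groups = cut_dendrogram(average_linkage(bray_curtis(rpkm, "samples")), sample_cut)
    candidates = []
    for taxa in taxon_groups:
        for samples in sample_groups:
            block = rpkm.loc[sorted(taxa), sorted(samples)].values
            elevation = float(np.median(block)) / global_median
            if elevation >= elevation_min:
                candidates.append((elevation, taxa, samples))
    candidates.sort(key=lambda c: (-c[0], sorted(c[1])[0]))
    letters = _cluster_labels(len(candidates))
    return [EcologicalCluster(label=letters[i], taxa=t, samples=s, elevation=e)
            for i, (e, t, s) in enumerate(candidates)]


def _cluster_labels(n: int) -> list[str]:
    out = []
    for i in range(n):
        lab = ""
        k = i
        while True:
            lab = chr(ord("A") + k % 26) + lab
            k = k // 26 - 1
            if k < 0:
                break
        out.append(lab)
    return out


@dataclass
class CCAResult:
    eigenvalues: np.ndarray          # constrained eigenvalues, non-increasing
    axis_fractions: np.ndarray       # eigenvalue / total constrained inertia
    constrained_inertia: float
    total_inertia: float
    site_scores: pd.DataFrame        # samples x axes
    species_scores: pd.DataFrame     # taxa x axes
    variables: list[str]


def cca(abundance: pd.DataFrame, env: pd.DataFrame,
        collinearity_tol: float = 1e-8) -> CCAResult:
    """Canonical correspondence analysis (samples x taxa vs samples x vars).

    Samples with any missing variable are dropped (complete-case analysis);
    environmental variables are z-standardized; a variable (nearly) collinear
    with the preceding ones is dropped with a warning.  The decomposition
    follows the classical chi-square formulation: the standardized abundance
    residual matrix is projected onto the row-weighted environmental space
    and eigen-decomposed; axis percentages are eigenvalues over the total
    constrained inertia.
    """
    env = env.dropna(axis=0, how="any")
    common = [s for s in abundance.index if s in env.index]
    dropped = len(abundance.index) - len(common)
    if dropped:
        logger.info("dropping %d samples with incomplete environmental data", dropped)
    y = abundance.loc[common]
    y = y.loc[y.sum(axis=1) > 0, y.sum(axis=0) > 0]
    z = env.loc[y.index].astype(float)
    if z.shape[1] < 2:
        raise ValueError("need at least 2 environmental variables")
    total = float(y.values.sum())
    p = y.values / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    q = (p - expected) / np.sqrt(expected)
    total_inertia = float((q ** 2).sum())
    # z-standardize, then weight rows by sqrt(r) and drop collinear columns
    zs = (z - z.mean()) / z.std(ddof=0)
    keep, x_cols = [], []
    xw = np.sqrt(r)[:, None] * zs.values
    # weighted centering so the constrained space excludes the trivial axis
    xw_c = xw - np.sqrt(r)[:, None] * (r @ zs.values)[None, :]
    for j, name in enumerate(zs.columns):
        col = xw_c[:, j]
        if x_cols:
            basis = np.column_stack(x_cols)
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
        else:
            resid = col
        if np.linalg.norm(resid) <= collinearity_tol * max(1.0, np.linalg.norm(col)):
            logger.warning("dropping collinear environmental variable %r", name)
            continue
        keep.append(name)
        x_cols.append(col)
    x = np.column_stack(x_cols)
    # project Q onto the environmental space: Q_fit = X (X'X)^-1 X' Q
    beta, *_ = np.linalg.lstsq(x, q, rcond=None)
    q_fit = x @ beta
    u, s, vt = np.linalg.svd(q_fit, full_matrices=False)
    eig = s ** 2
    rank = min(len(keep), y.shape[1] - 1)
    eig = eig[:rank]
    order = np.argsort(eig)[::-1]
    eig = eig[order]
    constrained = float(eig.sum())
    fractions = eig / constrained if constrained > 0 else np.zeros_like(eig)
    axes = [f"CCA{i + 1}" for i in range(len(eig))]
    site = (u[:, order] / np.sqrt(r)[:, None])[:, : len(eig)]
    species = (vt.T[:, order] / np.sqrt(c)[:, None])[:, : len(eig)]
    return CCAResult(
        eigenvalues=eig, axis_fractions=fractions,
        constrained_inertia=constrained, total_inertia=total_inertia,
        site_scores=pd.DataFrame(site, index=y.index, columns=axes),
        species_scores=pd.DataFrame(species, index=y.columns, columns=axes),
        variables=keep,
    )


def _pseudo_f(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    n = d2.shape[0]
    a = len(group_indices)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for idx in group_indices:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):
        # perfect within-group homogeneity gives an infinite pseudo-F
        return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(dist: DistanceMatrix, groups: dict[str, str] | pd.Series,
              n_perm: int = DEFAULT_N_PERM, seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F on squared distances, permutation p-value.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm) under uniform
    unrestricted label permutation; every group must have >= 2 members.
    """
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    labels = np.array([str(groups[l]) for l in dist.labels])
    names, inverse = np.unique(labels, return_inverse=True)
    if len(names) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(inverse)
    if (sizes < 2).any():
        small = [names[i] for i in np.where(sizes < 2)[0]]
        raise ValueError(f"every group needs >= 2 members; too small: {small}")
    d2 = dist.data ** 2
    observed_idx = [np.where(inverse == g)[0] for g in range(len(names))]
    f_obs = _pseudo_f(d2, observed_idx)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(inverse)
        idx = [np.where(perm == g)[0] for g in range(len(names))]
        if _pseudo_f(d2, idx) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), p=float(p), n_permutations=n_perm,
                           groups=list(names), seed=seed)


def pairwise_permanova(dist: DistanceMatrix, groups: dict[str, str] | pd.Series,
                       n_perm: int = DEFAULT_N_PERM,
                       seed: int | None = None) -> pd.DataFrame:
    """PERMANOVA for every pair of groups, permuting within the pair's
    subset, with Bonferroni-adjusted p (multiplier = number of pairs)."""
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    by_group: dict[str, list[str]] = {}
    for lab in dist.labels:
        by_group.setdefault(str(groups[lab]), []).append(lab)
    names = sorted(by_group)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        subset = by_group[a] + by_group[b]
        pos = [dist.labels.index(s) for s in subset]
        sub = DistanceMatrix(dist.data[np.ix_(pos, pos)], subset)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = permanova(sub, {s: groups[s] for s in subset},
                        n_perm=n_perm, seed=sub_seed)
        rows.append({"group_a": a, "group_b": b, "pseudo_f": res.pseudo_f,
                     "p": res.p, "p_bonferroni": min(1.0, res.p * len(pairs)),
                     "n_permutations": n_perm})
    return pd.DataFrame(rows)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adjusted[i] = running_min
    return adjusted


# Environmental bins exactly as used for the PERMANOVA groupings.  Printed
# ranges are closed on their printed endpoints; values falling in the gaps
# between printed ranges (e.g. oxygen 159-160) go to the nearer range's edge
# bin, ties to the lower bin.
_BIN_SPECS = {
    "temperature": [("<10", None, 10, False, False), ("10-20", 10, 20, True, True),
                    (">20", 20, None, False, False)],
    "oxygen": [("<110", None, 110, False, False), ("110-159", 110, 159, True, True),
               ("160-200", 160, 200, True, True), (">200", 200, None, False, False)],
    "phosphate": [("<0.5", None, 0.5, False, False), ("0.5-2.0", 0.5, 2.0, True, True),
                  (">2.0", 2.0, None, False, False)],
    "nitrate": [("<0.5", None, 0.5, False, False), ("0.5-1.9", 0.5, 1.9, True, True),
                ("2.0-5.0", 2.0, 5.0, True, True), (">5.0", 5.0, None, False, False)],
}
_HAS_BDL = {"phosphate", "nitrate"}
_CONCENTRATIONS = {"oxygen", "phosphate", "nitrate"}


def _bin_value(value: float, specs) -> str:
    for name, lo, hi, lo_closed, hi_closed in specs:
        lo_ok = lo is None or (value >= lo if lo_closed else value > lo)
        hi_ok = hi is None or (value <= hi if hi_closed else value < hi)
        if lo_ok and hi_ok:
            return name
    # value in a gap between printed ranges: nearest edge, ties downward
    best = None
    for name, lo, hi, _lc, _hc in specs:
        for edge in (lo, hi):
            if edge is None:
                continue
            key = (abs(value - edge), edge)
            if best is None or key < best[0]:
                best = (key, name)
    return best[1]


def bin_environment(metadata: pd.DataFrame) -> pd.DataFrame:
    """Bin each recognized variable into its fixed PERMANOVA groups.

    Cells may be numeric, the string ``"BDL"`` (below detection limit — its
    own category for phosphate and nitrate), or missing (NaN -> left unbinned
    so the sample drops out of that variable's test).  Negative
    concentrations are rejected.
    """
    out = {}
    for var in metadata.columns:
        if var not in _BIN_SPECS:
            continue
        labels = []
        for val in metadata[var]:
            if isinstance(val, str) and val.strip().upper() == BDL:
                if var not in _HAS_BDL:
                    raise ValueError(f"BDL is not a category for {var}")
                labels.append(BDL)
                continue
            fval = float(val)
            if np.isnan(fval):
                labels.append(np.nan)
                continue
            if var in _CONCENTRATIONS and fval < 0:
                raise ValueError(f"negative {var} concentration: {fval}")
            labels.append(_bin_value(fval, _BIN_SPECS[var]))
        out[var] = labels
    return pd.DataFrame(out, index=metadata.index)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample, two-sided t-test: (t, Welch-Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
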