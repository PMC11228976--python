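"""Comparative statistics over an EPep LFQ matrix.

Per-species EPep counts with one-way ANOVA, Tukey HSD and a compact-letter
display; Bonferroni-adjusted pairwise t-tests; exact multi-set overlap
(Venn region) counts; PCA and ward.D2 hierarchical clustering of
ln-transformed mean LFQ intensities with explicit missing-value policies;
epitope/group/protein-type sliced matrices; and the prevalence-filtered,
row-scaled quantitative comparison.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "SpeciesCountSummary",
    "PcaResult",
    "ClusterResult",
    "count_epeps",
    "anova_tukey",
    "compact_letter_display",
    "pairwise_t_bonferroni",
    "species_overlap",
    "ln_impute",
    "pca_lfq",
    "hcluster",
    "subset_analysis",
    "prevalence_filter_and_scale",
]


# ---------------------------------------------------------------- counts

@dataclass
class SpeciesCountSummary:
    per_sample: pd.DataFrame  # sample_id, species, cultivar, n_epeps
    per_species: pd.DataFrame  # species, mean, sd[, letter]
    anova: dict = field(default_factory=dict)


def count_epeps(matrix, design=None) -> SpeciesCountSummary:
    """Distinct EPeps per sample (nonmissing cells per column) and the
    per-species mean +- SD over cultivars (n-1 denominator)."""
    design = design or matrix.design
    counts = matrix.sample_counts()
    per_sample = pd.DataFrame(
        {
            "sample_id": design.sample_ids,
            "species": [design.species_of(s) for s in design.sample_ids],
            "cultivar": [cv for _, _, cv in design.samples],
            "n_epeps": [int(counts[s]) for s in design.sample_ids],
        }
    )
    per_species = (
        per_sample.groupby("species", sort=False)["n_epeps"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1))
        .reindex(design.species_order)
        .reset_index()
    )
    return SpeciesCountSummary(per_sample=per_sample, per_species=per_species)


# ---------------------------------------------------------------- ANOVA / Tukey

def compact_letter_display(
    groups: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Groups sharing a letter are not significantly different; significantly
    different pairs never share a letter. Letters are assigned
    alphabetically in the supplied group order.
    """
    # letter columns as sets of group indices
    cols: list[set[int]] = [set(range(len(groups)))]
    idx = {g: i for i, g in enumerate(groups)}

    def sig(i: int, j: int) -> bool:
        a, b = groups[i], groups[j]
        return significant.get((a, b), significant.get((b, a), False))

    for i, j in itertools.combinations(range(len(groups)), 2):
        if not sig(i, j):
            continue
        for col in [c for c in cols if i in c and j in c]:
            cols.remove(col)
            new_i, new_j = col - {j}, col - {i}
            for new in (new_i, new_j):
                if not any(new <= c for c in cols):
                    cols.append(new)
    # absorb: drop columns contained in another
    cols = [c for c in cols if not any(c < d for d in cols)]
    # order columns by smallest member for stable alphabetical assignment
    cols.sort(key=lambda c: sorted(c))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", cols):
        for i in sorted(col):
            letters[groups[i]] += letter
    return letters


def anova_tukey(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    alpha: float = 0.05,
    group_order: list[str] | None = None,
) -> dict:
    """One-way ANOVA plus Tukey HSD pairwise comparisons and compact
    letters. Pairs with adjusted p exactly equal to alpha count as not
    significant."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    order = group_order or list(dict.fromkeys(groups))
    arrays = [values[groups == g] for g in order]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance everywhere; ANOVA undefined")
    f_stat, p_value = sps.f_oneway(*arrays)
    tuk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    tukey = pd.DataFrame(
        tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
    )
    significant = {}
    for _, row in tukey.iterrows():
        pair = (str(row["group1"]), str(row["group2"]))
        significant[pair] = float(row["p-adj"]) < alpha
    letters = compact_letter_display(order, significant)
    return {
        "f_stat": float(f_stat),
        "p_value": float(p_value),
        "tukey": tukey,
        "letters": letters,
        "alpha": alpha,
    }


def pairwise_t_bonferroni(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """All pairwise two-sample t-tests with Bonferroni adjustment
    (p_adj = min(1, p * n_comparisons)); pairs involving a singleton group
    are reported with NaN p-values."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    order = group_order or list(dict.fromkeys(groups))
    pairs = list(itertools.combinations(order, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = values[groups == a], values[groups == b]
        if len(xa) < 2 or len(xb) < 2:
            p = np.nan
        else:
            p = float(sps.ttest_ind(xa, xb).pvalue)
        rows.append(
            {
                "group1": a,
                "group2": b,
                "p_raw": p,
                "p_adj": min(1.0, p * m) if np.isfinite(p) else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- overlaps

def species_overlap(sets: dict[str, set]) -> pd.DataFrame:
    """Exact region counts for all 2^k - 1 regions of k named sets.

    Each row: bitmask over species (bit i = species i in the region's
    "inside" set), the member species, and the number of elements exactly in
    those sets and no others. Region counts sum to the union size.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need >= 2 sets")
    if len(names) > 6:
        raise ValueError("exact region enumeration supported for k <= 6")
    universe = set().union(*sets.values())
    membership: dict[frozenset, int] = {}
    for el in universe:
        key = frozenset(n for n in names if el in sets[n])
        membership[key] = membership.get(key, 0) + 1
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            key = frozenset(combo)
            mask = sum(1 << i for i, n in enumerate(names) if n in key)
            rows.append(
                {
                    "bitmask": mask,
                    "species": ";".join(combo),
                    "count": membership.get(key, 0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- PCA / clustering

def ln_impute(values: pd.DataFrame, impute_policy: str = "halfmin") -> pd.DataFrame:
    """ln-transform positive intensities and fill missing cells.

    Policies: ``halfmin`` (ln of half the global minimum observed intensity,
    a standard LFQ detection floor), ``zero`` (fill ln-value 0) and
    ``rowmean`` (row mean of observed ln-values). All-missing rows are
    dropped with a warning.
    """
    keep = values.notna().any(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} all-missing row(s)")
        values = values.loc[keep]
    ln = np.log(values)
    if impute_policy == "halfmin":
        floor = np.log(np.nanmin(values.to_numpy()) / 2.0)
        return ln.fillna(floor)
    if impute_policy == "zero":
        return ln.fillna(0.0)
    if impute_policy == "rowmean":
        return ln.apply(lambda r: r.fillna(r.mean()), axis=1)
    raise ValueError(f"unknown impute policy {impute_policy!r}")


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray


def pca_lfq(matrix, impute_policy: str = "halfmin", n_components: int | None = None) -> PcaResult:
    """PCA of samples over ln-transformed, imputed mean LFQ intensities
    (samples as observations, EPeps as variables, column-centered)."""
    values = matrix.values if hasattr(matrix, "values") and not isinstance(matrix, pd.DataFrame) else matrix
    ln = ln_impute(values, impute_policy)
    X = ln.to_numpy().T  # samples x features
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=ln.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    def flat_clusters(self, k: int) -> dict[str, int]:
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hcluster(matrix, axis: str = "columns", impute_policy: str = "halfmin") -> ClusterResult:
    """Ward.D2 hierarchical clustering (ward linkage on Euclidean distances
    of ln-transformed, imputed values) over samples (``columns``) or EPeps
    (``rows``). Ties break deterministically by input order."""
    values = matrix.values if hasattr(matrix, "values") and not isinstance(matrix, pd.DataFrame) else matrix
    ln = ln_impute(values, impute_policy)
    if axis == "columns":
        X, labels = ln.to_numpy().T, list(ln.columns)
    elif axis == "rows":
        X, labels = ln.to_numpy(), list(ln.index)
    else:
        raise ValueError("axis must be 'rows' or 'columns'")
    if len(labels) < 2:
        return ClusterResult(linkage=np.empty((0, 4)), labels=labels)
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="ward")
    return ClusterResult(linkage=Z, labels=labels)


# ---------------------------------------------------------------- slicing / scaling

def subset_analysis(matrix, epitope: str | None = None, group: int | None = None,
                    protein_type: str | None = None):
    """Slice the matrix to EPeps matching one selector: a single epitope, an
    epitope group, or a gluten protein type. Empty slices are allowed."""
    from .quant import LFQMatrix

    ann = matrix.row_annotations
    selectors = [x is not None for x in (epitope, group, protein_type)]
    if sum(selectors) != 1:
        raise ValueError("specify exactly one of epitope=, group=, protein_type=")
    if epitope is not None:
        if not epitope or not epitope.isalpha():
            raise ValueError(f"unknown epitope selector {epitope!r}")
        mask = ann["epitopes"].str.split(";").map(lambda xs: epitope in xs)
    elif group is not None:
        if int(group) not in range(1, 6):
            raise ValueError(f"unknown epitope group {group!r}")
        mask = ann["groups"].str.split(";").map(lambda xs: str(group) in xs)
    else:
        known_types = {"glia-alpha", "glia-gamma", "glia-omega", "glut-L", "glut-H",
                       "hor", "sec", "ave"}
        if protein_type not in known_types:
            raise ValueError(f"unknown protein type {protein_type!r}")
        mask = ann["protein_types"].str.split(";").map(lambda xs: protein_type in xs)
    return LFQMatrix(
        values=matrix.values.loc[mask.to_numpy()],
        row_annotations=ann.loc[mask.to_numpy()],
        design=matrix.design,
    )


def prevalence_filter_and_scale(matrix, min_samples: int = 30):
    """Quantitative-comparison preprocessing: keep rows present in strictly
    more than ``min_samples`` samples, then z-score each row's ln-values
    over its nonmissing cells (mean 0, SD 1, n-1 denominator). Constant
    retained rows become all-zero with a warning."""
    from .quant import LFQMatrix

    presence = matrix.presence
    keep = presence.sum(axis=1) > min_samples
    values = matrix.values.loc[keep]
    ln = np.log(values)
    mean = ln.mean(axis=1)
    sd = ln.std(axis=1, ddof=1)
    const = sd.fillna(0.0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant row(s) scaled to all-zero")
    sd = sd.where(~const)
    scaled = ln.sub(mean, axis=0).div(sd, axis=0)
    scaled.loc[const] = 0.0
    scaled = scaled.where(ln.notna())
    return LFQMatrix(
        values=scaled,
        row_annotations=matrix.row_annotations.loc[keep],
        design=matrix.design,
    )
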