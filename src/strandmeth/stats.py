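"""Paired methylation comparisons, strand-bias analysis, clustering.

The central object is :class:`PairedMethylationModel`: a model for
per-(donor, CpG) differences in percent methylation between two paired
conditions (two cell populations of the same donors, or the two strands
of the same region).  The model is

    diff[d, c] = mu + a_d + b_c + e[d, c]

with crossed random intercepts for donor (``a_d``) and CpG position
(``b_c``); the scientific question is whether the fixed intercept
``mu`` — the population-level mean methylation difference in percentage
points — is zero.  ``fit()`` returns a :class:`PairedComparisonResult`
with the estimate, its standard error, the p-value and a ``summary()``
table.  Three inference methods are offered:

``moment`` (default)
    Method-of-moments fit of the crossed random-intercepts model.  The
    variance of the grand mean is estimated as ``var(donor means)/D +
    (MSB - MSE)+/(DC)`` — the donor-mean term already carries the donor
    and residual components, the positive-part term adds the CpG
    component — and the Wald statistic is referred to a t distribution
    with D-1 degrees of freedom.  Chosen because the REML Wald test is
    markedly conservative when the true variance components are near
    zero (boundary truncation inflates the intercept SE).
``reml``
    REML fit of the same model via :mod:`statsmodels` ``MixedLM`` with
    two variance components, Wald z test on the intercept.
``permutation``
    Donor-level sign-flip permutation: all of a donor's differences are
    flipped jointly, which respects within-donor correlation.  Exact
    (exhaustive over the 2^D sign patterns) when feasible.

Significance is declared against the Bonferroni-adjusted threshold
(default family alpha 0.05 over 3 comparisons, the three Treg-vs-Tcon
contrasts sharing one Tcon sample).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .calling import MethylationMatrix

__all__ = [
    "BonferroniAlpha",
    "bonferroni_alpha",
    "region_average",
    "paired_difference_table",
    "PairedMethylationModel",
    "PairedComparisonResult",
    "mixed_effects_test",
    "permutation_test",
    "StrandBiasResult",
    "strand_bias_analysis",
    "strand_bias_from_percents",
    "ClusterResult",
    "cluster_subtypes",
    "average_matrix_by_subtype",
]


@dataclass(frozen=True)
class BonferroniAlpha:
    """Bonferroni-adjusted significance threshold.

    ``reported`` is floored to 3 decimals (the printed criterion, e.g.
    0.05/3 -> 0.016); ``raw`` keeps full precision and is what
    comparisons use.
    """

    reported: float
    raw: float

    def __float__(self) -> float:
        return self.raw


def bonferroni_alpha(family_alpha: float, n_comparisons: int) -> BonferroniAlpha:
    """Per-comparison threshold ``family_alpha / n_comparisons``."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    raw = family_alpha / n_comparisons
    return BonferroniAlpha(reported=np.floor(raw * 1000) / 1000, raw=raw)


def region_average(
    matrix: MethylationMatrix | np.ndarray, cpg_subset: Sequence[int] | None = None
) -> float:
    """Unweighted mean percent methylation over a subset of CpGs.

    ``cpg_subset`` uses the 1-based CpG ordinals of the lollipop
    convention; None averages all CpGs.  CpGs with a zero denominator
    (NaN percent) are excluded with a warning.
    """
    percent = matrix.percent if isinstance(matrix, MethylationMatrix) else np.asarray(matrix, float)
    n = percent.size
    if cpg_subset is None:
        idx = np.arange(n)
    else:
        idx = np.asarray(list(cpg_subset), dtype=int) - 1
        if idx.size == 0:
            raise ValueError("cpg_subset must be non-empty")
        if idx.min() < 0 or idx.max() >= n:
            raise ValueError(f"cpg_subset out of range 1..{n}")
    vals = percent[idx]
    if np.isnan(vals).any():
        warnings.warn("excluding CpG(s) with zero denominator from region average")
        vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no CpGs with called clones in subset")
    return float(vals.mean())


def paired_difference_table(
    matrices: Mapping[tuple[str, str, str, str], MethylationMatrix],
    pop_a: str,
    pop_b: str,
) -> pd.DataFrame:
    """Long table of per-(donor, CpG) differences ``pop_a - pop_b``.

    ``matrices`` is keyed by (donor, population, region, strand); both
    populations must be present for a donor to contribute, and all
    matrices must share one region and strand.
    """
    regions = {(k[2], k[3]) for k in matrices}
    if len(regions) != 1:
        raise ValueError(f"matrices span multiple region/strand combinations: {sorted(regions)}")
    region, strand = regions.pop()
    donors_a = {k[0] for k in matrices if k[1] == pop_a}
    donors_b = {k[0] for k in matrices if k[1] == pop_b}
    shared = sorted(donors_a & donors_b)
    if not shared:
        raise ValueError(f"no donors with both populations {pop_a!r} and {pop_b!r}")
    rows = []
    for donor in shared:
        pa = matrices[(donor, pop_a, region, strand)].percent
        pb = matrices[(donor, pop_b, region, strand)].percent
        if pa.size != pb.size:
            raise ValueError(f"CpG count mismatch for donor {donor}")
        for c, d in enumerate(pa - pb, start=1):
            rows.append({"donor": donor, "cpg": c, "diff": d})
    return pd.DataFrame(rows)


@dataclass
class PairedComparisonResult:
    """Estimate and test of a paired methylation difference.

    All effects are in percentage points.  ``significant`` compares the
    p-value against the raw Bonferroni-adjusted threshold
    (``alpha_adjusted``); ``alpha_reported`` is the printed, floored
    form of the same threshold.
    """

    contrast: str
    mean_difference: float
    standard_error: float | None
    p_value: float
    alpha_adjusted: float
    alpha_reported: float
    n_donors: int
    n_cpgs: int
    method: str
    df: float | None = None
    note: str | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted

    def summary(self) -> str:
        lines = [
            "Paired methylation comparison",
            "=" * 46,
            f"contrast:            {self.contrast}",
            f"method:              {self.method}",
            f"n donors / n CpGs:   {self.n_donors} / {self.n_cpgs}",
            f"mean difference:     {self.mean_difference:+.2f} percentage points",
            f"standard error:      "
            + (f"{self.standard_error:.3f}" if self.standard_error is not None else "n/a"),
            f"p-value:             {self.p_value:.4g}",
            f"alpha (Bonferroni):  {self.alpha_reported:g} (raw {self.alpha_adjusted:.4g})",
            f"significant:         {self.significant}",
        ]
        if self.note:
            lines.append(f"note:                {self.note}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "mean_difference": self.mean_difference,
            "standard_error": self.standard_error,
            "p_value": self.p_value,
            "alpha_adjusted": self.alpha_adjusted,
            "alpha_reported": self.alpha_reported,
            "significant": self.significant,
            "n_donors": self.n_donors,
            "n_cpgs": self.n_cpgs,
            "method": self.method,
            "df": self.df,
            "note": self.note,
        }


class PairedMethylationModel:
    """Crossed random-intercepts model for paired methylation differences.

    Parameters
    ----------
    diff_table
        Long DataFrame with columns ``donor``, ``cpg``, ``diff``
        (percentage points), one row per donor x CpG cell.
    contrast
        Label for the comparison (e.g. ``"Tcon - CD45RA-CD15s+"`` or
        ``"top - bottom"``).
    """

    def __init__(self, diff_table: pd.DataFrame, contrast: str = "a - b"):
        required = {"donor", "cpg", "diff"}
        if not required.issubset(diff_table.columns):
            raise ValueError(f"diff_table must have columns {sorted(required)}")
        self.table = diff_table.reset_index(drop=True)
        self.contrast = contrast
        self.pivot = self.table.pivot_table(index="donor", columns="cpg", values="diff")
        if self.pivot.shape[0] < 2 or self.pivot.shape[1] < 1:
            raise ValueError("need >= 2 donors and >= 1 CpG")
        if self.pivot.isna().any().any():
            warnings.warn("mean-imputing missing donor x CpG cells per CpG")
            self.pivot = self.pivot.apply(lambda col: col.fillna(col.mean()), axis=0)

    @classmethod
    def from_matrices(
        cls,
        matrices: Mapping[tuple[str, str, str, str], MethylationMatrix],
        pop_a: str,
        pop_b: str,
    ) -> "PairedMethylationModel":
        table = paired_difference_table(matrices, pop_a, pop_b)
        return cls(table, contrast=f"{pop_a} - {pop_b}")

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        method: str = "moment",
        alpha: float = 0.05,
        n_comparisons: int = 3,
        n_perm: int = 10000,
        seed: int | None = 0,
    ) -> PairedComparisonResult:
        """Estimate the mean difference and test it against zero."""
        thr = bonferroni_alpha(alpha, n_comparisons)
        y = self.pivot.to_numpy(float)
        if np.all(y == 0):
            return self._result(0.0, 0.0, 1.0, thr, "degenerate", note="all differences zero")
        if method == "moment":
            if np.allclose(y, y.flat[0]):
                res = self._fit_permutation(thr, n_perm, seed)
                res.note = "zero-variance table; fell back to sign-flip permutation"
                return res
            if y.shape[1] < 2:
                res = self._fit_permutation(thr, n_perm, seed)
                res.note = "single CpG; fell back to sign-flip permutation"
                return res
            return self._fit_moment(thr)
        if method == "reml":
            return self._fit_reml(thr, n_perm, seed)
        if method == "permutation":
            return self._fit_permutation(thr, n_perm, seed)
        raise ValueError(f"unknown method {method!r}")

    def _result(self, est, se, p, thr: BonferroniAlpha, method, df=None, note=None):
        return PairedComparisonResult(
            contrast=self.contrast,
            mean_difference=float(est),
            standard_error=None if se is None else float(se),
            p_value=float(p),
            alpha_adjusted=thr.raw,
            alpha_reported=thr.reported,
            n_donors=self.pivot.shape[0],
            n_cpgs=self.pivot.shape[1],
            method=method,
            df=df,
            note=note,
        )

    def _fit_moment(self, thr: BonferroniAlpha) -> PairedComparisonResult:
        y = self.pivot.to_numpy(float)
        D, C = y.shape
        gm = y.mean()
        donor_means = y.mean(axis=1)
        cpg_means = y.mean(axis=0)
        s2_dm = donor_means.var(ddof=1) / D
        msb = D * ((cpg_means - gm) ** 2).sum() / (C - 1)
        resid = y - donor_means[:, None] - cpg_means[None, :] + gm
        mse = (resid**2).sum() / ((D - 1) * (C - 1))
        v = s2_dm + max(msb - mse, 0.0) / (D * C)
        if v <= 0:
            # all rows identical but table not constant: residual floor
            v = max(mse / (D * C), np.finfo(float).tiny)
        t = gm / np.sqrt(v)
        p = 2 * sps.t.sf(abs(t), D - 1)
        return self._result(gm, np.sqrt(v), p, thr, "mixed_effects", df=D - 1)

    def _fit_reml(self, thr: BonferroniAlpha, n_perm: int, seed) -> PairedComparisonResult:
        from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        y = self.pivot.to_numpy(float)
        D, C = y.shape
        endog = y.ravel()
        donor_dum = np.kron(np.eye(D), np.ones((C, 1)))
        cpg_dum = np.kron(np.ones((D, 1)), np.eye(C))
        vcs = VCSpec(
            names=["donor", "cpg"],
            colnames=[[str(d) for d in self.pivot.index], [str(c) for c in self.pivot.columns]],
            mats=[[donor_dum], [cpg_dum]],
        )
        exog = np.ones((endog.size, 1))
        groups = np.zeros(endog.size)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                res = MixedLM(endog, exog, groups=groups, exog_vc=vcs).fit(reml=True)
            if not np.isfinite(res.bse[0]) or res.bse[0] <= 0:
                raise ValueError("singular fit")
        except Exception:
            out = self._fit_permutation(thr, n_perm, seed)
            out.note = "singular REML fit; fell back to sign-flip permutation"
            return out
        return self._result(
            res.params[0], res.bse[0], res.pvalues[0], thr, "mixed_effects_reml"
        )

    def _fit_permutation(self, thr: BonferroniAlpha, n_perm: int, seed) -> PairedComparisonResult:
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
        y = self.pivot.to_numpy(float)
        D, _ = y.shape
        donor_means = y.mean(axis=1)
        obs = donor_means.mean()
        tol = 1e-9 * (1 + abs(obs))
        if D <= 20 and 2**D <= n_perm:
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=D)))
            stats_perm = signs @ donor_means / D
            p = float(np.mean(np.abs(stats_perm) >= abs(obs) - tol))
        else:
            rng = np.random.default_rng(seed)
            signs = rng.choice((1.0, -1.0), size=(n_perm, D))
            stats_perm = signs @ donor_means / D
            p = float((1 + np.sum(np.abs(stats_perm) >= abs(obs) - tol)) / (1 + n_perm))
        return self._result(
            obs, donor_means.std(ddof=1) / np.sqrt(D), p, thr, "permutation"
        )


def mixed_effects_test(
    diff_table: pd.DataFrame,
    contrast: str = "a - b",
    alpha: float = 0.05,
    n_comparisons: int = 3,
    method: str = "moment",
) -> PairedComparisonResult:
    """Test a paired difference table against zero (crossed mixed model)."""
    return PairedMethylationModel(diff_table, contrast).fit(
        method=method, alpha=alpha, n_comparisons=n_comparisons
    )


def permutation_test(
    diff_table: pd.DataFrame,
    n_perm: int = 10000,
    seed: int | None = 0,
    contrast: str = "a - b",
    alpha: float = 0.05,
    n_comparisons: int = 3,
) -> PairedComparisonResult:
    """Donor-level sign-flip permutation test of a paired difference table.

    Flips all of a donor's differences jointly.  Exhaustive over the
    2^D sign patterns when that is no larger than ``n_perm`` (exact p);
    otherwise Monte Carlo with add-one correction, deterministic per
    seed.
    """
    return PairedMethylationModel(diff_table, contrast).fit(
        method="permutation", alpha=alpha, n_comparisons=n_comparisons,
        n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# Strand bias
# ---------------------------------------------------------------------------

@dataclass
class StrandBiasResult:
    """Per-CpG strand comparison plus the region-level paired test.

    Percentages are donor-averaged and reported in the top strand's
    5'->3' CpG order (the bottom strand's ordinals run antiparallel and
    are reversed to pair each CpG with itself).  The hemimethylation
    index is |top - bottom| in percentage points; ``signed`` keeps the
    direction (top - bottom).
    """

    region: str
    population: str
    top_percent: np.ndarray
    bottom_percent: np.ndarray
    comparison: PairedComparisonResult
    diff_table: pd.DataFrame = field(repr=False)

    @property
    def hemimethylation_index(self) -> np.ndarray:
        return np.abs(self.top_percent - self.bottom_percent)

    @property
    def signed(self) -> np.ndarray:
        return self.top_percent - self.bottom_percent

    @property
    def mean_index(self) -> float:
        return float(np.nanmean(self.hemimethylation_index))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region,
                "population": self.population,
                "cpg": np.arange(1, self.top_percent.size + 1),
                "top_percent": self.top_percent,
                "bottom_percent": self.bottom_percent,
                "hemimethylation_index": self.hemimethylation_index,
                "signed_difference": self.signed,
            }
        )


def strand_bias_from_percents(
    top: Mapping[str, np.ndarray],
    bottom: Mapping[str, np.ndarray],
    region: str,
    population: str,
    alpha: float = 0.05,
    n_comparisons: int = 3,
    method: str = "moment",
) -> StrandBiasResult:
    """Strand-bias analysis from per-donor percent vectors.

    ``top`` and ``bottom`` map donor -> per-CpG percent vector, each in
    its own strand's 5'->3' CpG order.  Bottom-strand vectors are
    reversed so each CpG is compared with itself (the two strands'
    ordinals run antiparallel over the same CpG dinucleotides).
    """
    shared = sorted(set(top) & set(bottom))
    if not shared:
        raise ValueError("no donors present on both strands")
    rows = []
    top_stack, bottom_stack = [], []
    for donor in shared:
        pt = np.asarray(top[donor], float)
        pb = np.asarray(bottom[donor], float)[::-1]  # antiparallel -> genomic pairing
        if pt.size != pb.size:
            raise ValueError(f"CpG count mismatch between strands for donor {donor}")
        top_stack.append(pt)
        bottom_stack.append(pb)
        for c, d in enumerate(pt - pb, start=1):
            rows.append({"donor": donor, "cpg": c, "diff": d})
    table = pd.DataFrame(rows)
    comparison = PairedMethylationModel(
        table, contrast=f"{region} {population}: top - bottom"
    ).fit(method=method, alpha=alpha, n_comparisons=n_comparisons)
    return StrandBiasResult(
        region=region,
        population=population,
        top_percent=np.nanmean(np.vstack(top_stack), axis=0),
        bottom_percent=np.nanmean(np.vstack(bottom_stack), axis=0),
        comparison=comparison,
        diff_table=table,
    )


def strand_bias_analysis(
    matrices_top: Sequence[MethylationMatrix],
    matrices_bottom: Sequence[MethylationMatrix],
    alpha: float = 0.05,
    n_comparisons: int = 3,
    method: str = "moment",
) -> StrandBiasResult:
    """Compare top- and bottom-strand methylation of one region/population.

    Inputs are per-donor matrices (one per strand per donor) for a
    single region and population.  Bottom-strand CpG columns are
    reversed so each CpG is compared with itself across strands; the
    region-level test is the crossed mixed model on per-(donor, CpG)
    top - bottom differences.
    """
    meta_top = {(m.group[1], m.group[2], m.group[3]) for m in matrices_top}
    meta_bot = {(m.group[1], m.group[2], m.group[3]) for m in matrices_bottom}
    if len(meta_top) != 1 or len(meta_bot) != 1:
        raise ValueError("each strand's matrices must share one population and region")
    pop_t, region_t, strand_t = meta_top.pop()
    pop_b, region_b, strand_b = meta_bot.pop()
    if strand_t != "top" or strand_b != "bottom":
        raise ValueError(f"expected top/bottom strand inputs, got {strand_t!r}/{strand_b!r}")
    if (pop_t, region_t) != (pop_b, region_b):
        raise ValueError("population/region mismatch between strands")
    return strand_bias_from_percents(
        {m.group[0]: m.percent for m in matrices_top},
        {m.group[0]: m.percent for m in matrices_bottom},
        region=region_t,
        population=pop_t,
        alpha=alpha,
        n_comparisons=n_comparisons,
        method=method,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering of cell subtypes
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Complete-linkage clustering of subtypes on average methylation."""

    labels: list[str]
    distance_matrix: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def outgroup(self) -> str | None:
        """The label merging alone in the final join, if the last merge
        joins a singleton (the subtype farthest from all others)."""
        n = len(self.labels)
        last = self.linkage[-1]
        for child in (int(last[0]), int(last[1])):
            if child < n:
                return self.labels[child]
        return None

    def newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


def cluster_subtypes(average_matrix: pd.DataFrame) -> ClusterResult:
    """Cluster cell subtypes on their average per-CpG methylation.

    ``average_matrix`` has one row per subtype, one column per CpG
    (donor-averaged percent methylation).  Euclidean distances,
    complete-linkage agglomeration; rows are sorted by label first so
    ties break deterministically by label order.  Missing values are
    mean-imputed per CpG with a warning.
    """
    if average_matrix.shape[0] < 2:
        raise ValueError("need at least 2 subtypes to cluster")
    mat = average_matrix.sort_index()
    if mat.isna().any().any():
        warnings.warn("mean-imputing missing per-CpG averages before clustering")
        mat = mat.apply(lambda col: col.fillna(col.mean()), axis=0)
    labels = [str(x) for x in mat.index]
    dvec = pdist(mat.to_numpy(float), metric="euclidean")
    linkage = hierarchy.linkage(dvec, method="complete")
    leaf_idx = hierarchy.leaves_list(linkage)
    dist = pd.DataFrame(squareform(dvec), index=labels, columns=labels)
    return ClusterResult(
        labels=labels,
        distance_matrix=dist,
        linkage=linkage,
        leaf_order=[labels[i] for i in leaf_idx],
    )


def average_matrix_by_subtype(
    matrices: Mapping[tuple[str, str, str, str], MethylationMatrix],
    region: str,
    strand: str,
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Donor-averaged percent methylation per subtype for one region/strand."""
    pops = sorted({k[1] for k in matrices if k[2] == region and k[3] == strand})
    if populations is not None:
        pops = [p for p in populations if p in pops]
    rows = {}
    for pop in pops:
        stack = [
            m.percent
            for k, m in matrices.items()
            if k[1] == pop and k[2] == region and k[3] == strand
        ]
        if stack:
            rows[pop] = np.nanmean(np.vstack(stack), axis=0)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"CpG_{i + 1}" for i in range(df.shape[1])]
    return df


def plot_heatmap(average_matrix: pd.DataFrame, path: str) -> None:
    """Optional heatmap of the subtype x CpG average methylation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, average_matrix.shape[1] * 0.4), 3))
    im = ax.imshow(average_matrix.to_numpy(float), aspect="auto", cmap="Blues", vmin=0, vmax=100)
    ax.set_yticks(range(average_matrix.shape[0]), average_matrix.index)
    ax.set_xticks(range(average_matrix.shape[1]), average_matrix.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="% methylation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
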