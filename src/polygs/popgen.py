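"""Quantitative- and population-genetic statistics for half-sib breeding data.

Three groups of tools:

* broad-sense heritability from one-way ANOVA of half-sib family plot
  values, with a delete-one jackknife standard deviation;
* linkage disequilibrium (composite r^2 on unphased codes) against a
  genetic map, binned decay curves and a GCV cubic smoothing spline;
* the training-population design chain: Sved's drift relation
  ``r^2 = 1/(4 Ne c + 1)`` inverted for the effective population size,
  the effective number of chromosome segments ``Me = 2 Ne L / ln(4 Ne L)``
  and the expected-accuracy equation ``r^2 = N h^2 / (N h^2 + Me)``
  solved either way.

All user-facing map distances are centimorgans; the Sved/Me formulas
take Morgans, so callers divide by 100 at that interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .genotype_io import GenotypeMatrix, MarkerMap, ValidationError

__all__ = [
    "VarianceComponents",
    "LDDecay",
    "heritability_anova",
    "jackknife_sd",
    "heritability_report",
    "pairwise_ld",
    "ld_decay_curve",
    "ld_heatmap",
    "sved_ne",
    "effective_segments",
    "expected_accuracy",
    "required_training_n",
]


# ---------------------------------------------------------------------------
# heritability


@dataclass
class VarianceComponents:
    """One-way ANOVA variance components for half-sib family data.

    ``h2`` is the broad-sense heritability sigma_G^2/(sigma_G^2+sigma_E^2);
    a negative method-of-moments genetic variance is clamped to zero so
    h2 always lies in [0, 1].
    """

    sigma_g2: float
    sigma_e2: float
    h2: float
    jackknife_sd: float | None = None


def _anova_components(values: np.ndarray, codes: np.ndarray, k: int):
    """Sums-of-squares decomposition; returns (sigma_g2, sigma_e2, h2).

    ``codes`` are integer family labels 0..k-1.  Unbalanced designs use
    the n0 coefficient n0 = (N - sum n_i^2 / N)/(k - 1).
    """
    n_total = values.size
    counts = np.bincount(codes, minlength=k).astype(float)
    sums = np.bincount(codes, weights=values, minlength=k)
    grand = values.sum() / n_total
    group_means = sums / counts
    ss_between = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(np.sum((values - group_means[codes]) ** 2))
    df_between = k - 1
    df_within = n_total - k
    if df_between < 1 or df_within < 1:
        raise ValueError(
            "need >=2 families and >=2 observations in at least one family"
        )
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    n0 = (n_total - np.sum(counts**2) / n_total) / df_between
    sigma_g2 = max((ms_between - ms_within) / n0, 0.0)
    sigma_e2 = ms_within
    if sigma_e2 == 0.0:
        # noiseless limit: identical values within families
        h2 = 1.0 if ms_between > 0 else 0.0
    else:
        h2 = sigma_g2 / (sigma_g2 + sigma_e2)
    return sigma_g2, sigma_e2, h2


def _encode_families(values, families):
    values = np.asarray(values, dtype=float)
    fam = pd.factorize(np.asarray(families))[0]
    if values.shape != fam.shape:
        raise ValueError("values and families must have equal length")
    if not np.isfinite(values).all():
        raise ValueError("non-finite trait value")
    return values, fam, fam.max() + 1 if fam.size else 0


def heritability_anova(values, families) -> VarianceComponents:
    """Broad-sense heritability from a one-way ANOVA over families.

    sigma_E^2 is the within-family mean square, sigma_G^2 the
    method-of-moments between-family component, H^2 their ratio.
    """
    values, fam, k = _encode_families(values, families)
    sigma_g2, sigma_e2, h2 = _anova_components(values, fam, k)
    return VarianceComponents(sigma_g2, sigma_e2, h2)


def jackknife_sd(values, families, statistic=None) -> float:
    """Delete-one-observation jackknife SD of the heritability estimate.

    SD = sqrt((n-1)/n * sum (theta_-i - mean theta_-i)^2).  Any
    leave-one-out subset that degenerates (a lone family, all singleton
    families) raises.
    """
    values, fam, k = _encode_families(values, families)
    n = values.size
    if statistic is None:
        statistic = lambda v, f: heritability_anova(v, f).h2  # noqa: E731
    thetas = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        try:
            thetas[i] = statistic(values[keep], fam[keep])
        except ValueError as exc:
            raise ValueError(f"leave-one-out subset {i} degenerate: {exc}") from exc
    return float(np.sqrt((n - 1) / n * np.sum((thetas - thetas.mean()) ** 2)))


def heritability_report(plots: pd.DataFrame, with_jackknife: bool = True) -> pd.DataFrame:
    """Per (trait, generation) heritability table from plot-level records.

    ``plots`` is long format with columns individual_id (the mother /
    family), generation, trait, value — one row per replicate plot.
    """
    rows = []
    for (trait, gen), sub in plots.groupby(["trait", "generation"], sort=True):
        vc = heritability_anova(sub["value"], sub["individual_id"])
        sd = (
            jackknife_sd(sub["value"], sub["individual_id"])
            if with_jackknife
            else np.nan
        )
        rows.append(
            {
                "trait": trait,
                "generation": gen,
                "sigma_G2": vc.sigma_g2,
                "sigma_E2": vc.sigma_e2,
                "H2": vc.h2,
                "jackknife_sd": sd,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linkage disequilibrium


@dataclass
class LDDecay:
    """All within-chromosome marker-pair LD values for one chromosome."""

    chromosome: int
    marker_i: list[str]
    marker_j: list[str]
    distance_cm: np.ndarray
    r2: np.ndarray
    adjacent_mean: float
    mean_adjacent_spacing_cm: float
    n_monomorphic: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "marker_i": self.marker_i,
                "marker_j": self.marker_j,
                "distance_cm": self.distance_cm,
                "r2": self.r2,
            }
        )


def pairwise_ld(g: GenotypeMatrix, marker_map: MarkerMap, chromosome: int) -> LDDecay:
    """Composite LD (squared Pearson correlation of -1/0/1 codes) for all
    marker pairs on one chromosome of the map.

    Monomorphic markers are excluded (count reported); adjacent-pair
    statistics are over consecutive retained markers in map order.
    """
    if g.has_missing():
        raise ValidationError("impute missing genotypes before LD")
    chrom = marker_map.chromosome_markers(chromosome)
    present = chrom[chrom["marker_id"].isin(g.marker_ids)]
    col = {m: i for i, m in enumerate(g.marker_ids)}
    idx = [col[m] for m in present["marker_id"]]
    codes = g.codes[:, idx]
    pos = present["position_cm"].to_numpy()
    names = present["marker_id"].tolist()

    poly = codes.std(axis=0) > 0
    n_mono = int((~poly).sum())
    codes, pos = codes[:, poly], pos[poly]
    names = [m for m, keep in zip(names, poly) if keep]
    m = len(names)
    if m < 2:
        raise ValidationError(
            f"chromosome {chromosome}: fewer than 2 polymorphic mapped markers"
        )

    corr = np.corrcoef(codes, rowvar=False)
    iu, ju = np.triu_indices(m, k=1)
    r2 = corr[iu, ju] ** 2
    dist = np.abs(pos[ju] - pos[iu])
    spacing = np.diff(pos)
    adjacent = corr[np.arange(m - 1), np.arange(1, m)] ** 2
    return LDDecay(
        chromosome=chromosome,
        marker_i=[names[i] for i in iu],
        marker_j=[names[j] for j in ju],
        distance_cm=dist,
        r2=r2,
        adjacent_mean=float(adjacent.mean()),
        mean_adjacent_spacing_cm=float(spacing.mean()),
        n_monomorphic=n_mono,
    )


def ld_decay_curve(decay: LDDecay, bin_width_cm: float = 5.0):
    """Distance-binned mean r^2 plus a cubic smoothing spline fit.

    The spline smoothing parameter is chosen by generalized
    cross-validation; duplicate distances are averaged (count-weighted)
    before fitting.  Empty bins are absent from the output rather than
    reported as zero.  Returns ``(bins, grid, fitted)``; the latter two
    are None when all pairs sit at a single distance.
    """
    if decay.r2.size < 10:
        raise ValueError("need at least 10 marker pairs for a decay curve")
    d, r2 = decay.distance_cm, decay.r2
    edges = np.arange(0.0, d.max() + bin_width_cm, bin_width_cm)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width_cm])
    which = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in np.unique(which):
        sel = which == b
        rows.append(
            {
                "bin_low_cm": edges[b],
                "bin_high_cm": edges[b + 1],
                "mean_distance_cm": d[sel].mean(),
                "mean_r2": r2[sel].mean(),
                "n_pairs": int(sel.sum()),
            }
        )
    bins = pd.DataFrame(rows)

    xs, inv = np.unique(d, return_inverse=True)
    if xs.size < 4:  # spline needs a real spread of distances
        return bins, None, None
    ys = np.bincount(inv, weights=r2) / np.bincount(inv)
    w = np.bincount(inv).astype(float)
    spline = make_smoothing_spline(xs, ys, w=w, lam=None)
    grid = np.linspace(xs[0], xs[-1], 200)
    return bins, grid, np.asarray(spline(grid))


def ld_heatmap(decay: LDDecay, path) -> None:
    """Export a simple marker x marker r^2 heat map (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = sorted(set(decay.marker_i) | set(decay.marker_j))
    pos = {m: i for i, m in enumerate(names)}
    mat = np.eye(len(names))
    for a, b, v in zip(decay.marker_i, decay.marker_j, decay.r2):
        mat[pos[a], pos[b]] = mat[pos[b], pos[a]] = v
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, vmin=0, vmax=1, cmap="viridis")
    ax.set_title(f"LD (r$^2$), chromosome {decay.chromosome}")
    fig.colorbar(im, ax=ax, label="r$^2$")
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# design formulas


def sved_ne(r2: float, c_morgans: float) -> float:
    """Effective population size from Sved's drift expectation.

    Inverts r^2 = 1/(4 Ne c + 1):  Ne = (1/r^2 - 1)/(4 c).
    ``c_morgans`` is the marker distance in Morgans (cM / 100).
    """
    if not 0 < r2 <= 1:
        raise ValueError(f"r2 must be in (0, 1], got {r2}")
    if c_morgans <= 0:
        raise ValueError(f"distance must be positive, got {c_morgans}")
    return (1.0 / r2 - 1.0) / (4.0 * c_morgans)


def effective_segments(ne: float, genome_length_morgans: float) -> float:
    """Effective number of independent chromosome segments.

    Me = 2 Ne L / ln(4 Ne L), with L the genome length in Morgans.
    """
    if ne <= 0 or genome_length_morgans <= 0:
        raise ValueError("Ne and L must be positive")
    x = 4.0 * ne * genome_length_morgans
    if x <= 1.0:
        raise ValueError(f"4*Ne*L must exceed 1 for a defined Me, got {x}")
    return 2.0 * ne * genome_length_morgans / math.log(x)


def expected_accuracy(n_train: float, h2: float, me: float) -> float:
    """Expected GEBV accuracy r = sqrt(N h^2 / (N h^2 + Me))."""
    if n_train <= 0 or me <= 0 or not 0 < h2 <= 1:
        raise ValueError("need N > 0, Me > 0 and h2 in (0, 1]")
    nh2 = n_train * h2
    return math.sqrt(nh2 / (nh2 + me))


def required_training_n(r2_target: float, h2: float, me: float) -> float:
    """Training-population size achieving squared accuracy ``r2_target``.

    Exact inverse of :func:`expected_accuracy`:
    N = Me r^2 / (h^2 (1 - r^2)).
    """
    if not 0 < r2_target < 1:
        raise ValueError(f"r2_target must be in (0, 1), got {r2_target}")
    if me <= 0 or not 0 < h2 <= 1:
        raise ValueError("need Me > 0 and h2 in (0, 1]")
    return me * r2_target / (h2 * (1.0 - r2_target))
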