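"""Catalog-level occupancy statistics.

Includes the pangenome growth-curve machinery: genomes are added in random
order (permutation experiments); for each prefix of g genomes the *core*
count is the number of pangenes present in all g and the *pan* count the
number present in at least one.  The core curve is summarised by an
exponential decay to an asymptote — either a single exponential
(Tettelin-style, ``omega + kappa*exp(-g/tau)``) or a two-component decay
(Willenbrock-style) — fitted by nonlinear least squares over all
permutation points; ``omega`` is the estimated core-genome size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .cluster import classify_occupancy
from .models import OccClass, PangeneMatrix, Subfamily, chrom_number


# ---------------------------------------------------------------------------
# histograms & counts
# ---------------------------------------------------------------------------

def occupancy_histogram(
    matrix: PangeneMatrix,
    drop_filter: Optional[Callable[[str], bool]] = None,
) -> Dict[int, int]:
    """Pangene counts per occupancy 1..panel_size.

    ``drop_filter`` is a gene-id predicate; pangenes whose *every* member
    satisfies it are excluded first (used to drop clusters made only of
    models from one inflating source, e.g. MSU-only singletons).
    """
    hist: Dict[int, int] = {}
    for p in matrix.pangenes:
        if drop_filter is not None and all(drop_filter(g) for g in p.gene_ids()):
            continue
        hist[p.occupancy] = hist.get(p.occupancy, 0) + 1
    return dict(sorted(hist.items()))


def singleton_counts_per_genome(
    matrix: PangeneMatrix,
    reference_filter: Optional[Tuple[str, Callable[[str], bool]]] = None,
) -> Dict[str, int]:
    """Per genome, number of singleton pangenes (clusters holding exactly
    one gene model) whose member belongs to that genome.

    ``reference_filter`` = (genome_id, gene-id predicate): for that genome
    only singletons whose member satisfies the predicate are counted
    (e.g. restrict the merged reference column to one source's models for
    unbiased comparison).
    """
    counts = {g: 0 for g in matrix.panel.genome_ids}
    if reference_filter is not None and reference_filter[0] not in counts:
        raise ValueError(f"unknown genome {reference_filter[0]!r} in filter")
    for p in matrix.pangenes:
        if not p.is_singleton:
            continue
        genome = next(iter(p.members))
        gene = p.members[genome][0]
        if reference_filter is not None and genome == reference_filter[0]:
            if not reference_filter[1](gene):
                continue
        counts[genome] += 1
    return counts


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

@dataclass
class PermutationCurve:
    n_permutations: int
    # one row per (permutation, g): genomes added, core count, pan count
    points: pd.DataFrame
    seed: int


@dataclass
class GrowthFit:
    model: str  # "tettelin" | "willenbrock"
    kappa: float
    tau: float
    omega: float
    extra: Dict[str, float] = field(default_factory=dict)
    residual_ss: float = 0.0


class GrowthFitError(RuntimeError):
    pass


def _presence_matrix(matrix: PangeneMatrix, exclude_singletons: bool) -> np.ndarray:
    genomes = matrix.panel.genome_ids
    idx = {g: i for i, g in enumerate(genomes)}
    rows = [p for p in matrix.pangenes if not (exclude_singletons and p.is_singleton)]
    P = np.zeros((len(rows), len(genomes)), dtype=bool)
    for r, p in enumerate(rows):
        for g in p.members:
            P[r, idx[g]] = True
    return P


def simulate_growth(
    matrix: PangeneMatrix,
    n_permutations: int = 20,
    exclude_singletons: bool = True,
    seed: int = 0,
) -> PermutationCurve:
    """Core/pan counts while genomes are added in random order."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n = matrix.panel_size
    if n < 2:
        raise ValueError("growth simulation needs a panel of >= 2 genomes")
    P = _presence_matrix(matrix, exclude_singletons)
    rng = np.random.default_rng(seed)
    records = []
    for perm in range(n_permutations):
        order = rng.permutation(n)
        core = np.ones(P.shape[0], dtype=bool)
        pan = np.zeros(P.shape[0], dtype=bool)
        for g, col in enumerate(order, start=1):
            core &= P[:, col]
            pan |= P[:, col]
            records.append((perm, g, int(core.sum()), int(pan.sum())))
    points = pd.DataFrame(records, columns=["permutation", "g", "core_count", "pan_count"])
    return PermutationCurve(n_permutations=n_permutations, points=points, seed=seed)


def _tettelin(g, omega, kappa, tau):
    return omega + kappa * np.exp(-g / tau)


def _willenbrock(g, omega, k1, t1, k2, t2):
    return omega + k1 * np.exp(-g / t1) + k2 * np.exp(-g / t2)


def fit_growth(
    curve: PermutationCurve,
    model: str = "tettelin",
    n_restarts: int = 10,
    seed: int = 0,
) -> GrowthFit:
    """Nonlinear least-squares fit of the core-count decay over all
    permutation points; 10 jittered restarts guard against local minima."""
    g = curve.points["g"].to_numpy(dtype=float)
    y = curve.points["core_count"].to_numpy(dtype=float)
    if len(np.unique(g)) < 3:
        raise GrowthFitError("need >= 3 distinct genome counts to fit")
    omega0 = float(y.min())
    kappa0 = max(float(y.max() - y.min()), 1.0)
    tau0 = max(len(np.unique(g)) / 4.0, 0.5)
    rng = np.random.default_rng(seed)

    # residual floor below which further restarts cannot help
    ss_floor = 1e-10 * max(float(np.sum(y**2)), 1.0)

    def attempt(func, p0, bounds):
        best = None
        for i in range(n_restarts):
            p = np.array(p0, dtype=float)
            if i > 0:
                p = p * rng.uniform(0.5, 1.5, size=len(p)) + 1e-6
                p = np.clip(p, [b + 1e-9 for b in bounds[0]], bounds[1])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(func, g, y, p0=p, bounds=bounds, maxfev=10000)
            except (RuntimeError, ValueError):
                continue
            ss = float(np.sum((func(g, *popt) - y) ** 2))
            if best is None or ss < best[1]:
                best = (popt, ss)
            if best[1] < ss_floor:
                break
        if best is None:
            raise GrowthFitError(
                f"{model} fit failed to converge after {n_restarts} restarts "
                f"(n={len(g)} points, core range {y.min():.0f}..{y.max():.0f})"
            )
        return best

    if model == "tettelin":
        popt, ss = attempt(
            _tettelin,
            [omega0, kappa0, tau0],
            ([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
        )
        return GrowthFit("tettelin", kappa=popt[1], tau=popt[2], omega=popt[0],
                         residual_ss=ss)
    if model == "willenbrock":
        try:
            base = fit_growth(curve, "tettelin", n_restarts=n_restarts, seed=seed)
            p0 = [base.omega, base.kappa * 0.7, base.tau, base.kappa * 0.3,
                  max(base.tau * 3, 1.0)]
        except GrowthFitError:
            p0 = [omega0, kappa0 * 0.7, tau0, kappa0 * 0.3, tau0 * 3]
        popt, ss = attempt(
            _willenbrock,
            p0,
            ([0.0, 0.0, 1e-6, 0.0, 1e-6], [np.inf] * 5),
        )
        return GrowthFit(
            "willenbrock", kappa=popt[1], tau=popt[2], omega=popt[0],
            extra={"kappa2": popt[3], "tau2": popt[4]}, residual_ss=ss,
        )
    raise ValueError(f"unknown growth model {model!r}")


# ---------------------------------------------------------------------------
# shared clusters, segregation, trans-chromosome rows
# ---------------------------------------------------------------------------

def shared_cluster_matrix(matrix: PangeneMatrix) -> pd.DataFrame:
    """Entry (i, j) = 100 * |clusters containing both genomes| /
    |clusters containing genome i|; diagonal 100; NaN for a genome in no
    cluster (reported via the NaN itself)."""
    genomes = matrix.panel.genome_ids
    idx = {g: i for i, g in enumerate(genomes)}
    P = np.zeros((len(matrix.pangenes), len(genomes)), dtype=bool)
    for r, p in enumerate(matrix.pangenes):
        for g in p.members:
            P[r, idx[g]] = True
    counts = P.T.astype(np.int64) @ P.astype(np.int64)
    totals = np.diag(counts).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * counts / totals[:, None]
    return pd.DataFrame(pct, index=genomes, columns=genomes)


def segregating_pangenes(
    matrix: PangeneMatrix,
    family: Subfamily | str,
    min_in: int,
    max_out: int,
) -> List[str]:
    """Pangenes with >= min_in member genomes inside the subfamily and
    <= max_out member genomes outside it (family-segregating genes)."""
    fam_genomes = set(matrix.panel.subfamily_members(family))
    if not fam_genomes:
        raise ValueError(f"subfamily {family!r} not in panel")
    if min_in > len(fam_genomes):
        raise ValueError(
            f"min_in {min_in} exceeds subfamily size {len(fam_genomes)}"
        )
    out: List[str] = []
    for i, p in enumerate(matrix.pangenes):
        inside = sum(1 for g in p.members if g in fam_genomes)
        outside = p.occupancy - inside
        if inside >= min_in and outside <= max_out:
            out.append(p.pangene_id if p.pangene_id is not None else str(i))
    return out


def trans_chromosome_pangenes(
    matrix: PangeneMatrix,
    positions: Mapping[str, Tuple[str, int]],
) -> Tuple[List[str], int]:
    """Pangenes with occupancy > 2 whose members map to different
    (normalized) chromosome numbers; returns (ids, n_skipped) where
    skipped rows lacked a position for some member."""
    hits: List[str] = []
    n_skipped = 0
    for i, p in enumerate(matrix.pangenes):
        if p.occupancy <= 2:
            continue
        chroms = set()
        ok = True
        for g in p.gene_ids():
            if g not in positions:
                warnings.warn(f"pangene row {i}: no position for gene {g}; skipped")
                n_skipped += 1
                ok = False
                break
            chroms.add(chrom_number(positions[g][0]))
        if ok and len(chroms) > 1:
            hits.append(p.pangene_id if p.pangene_id is not None else str(i))
    return hits, n_skipped


# ---------------------------------------------------------------------------
# evidence vs occupancy
# ---------------------------------------------------------------------------

@dataclass
class EvidenceComparison:
    field: str
    by_occupancy: pd.DataFrame  # mean/median/IQR/n per occupancy value
    by_class: pd.DataFrame      # mean/median/IQR/n per occupancy class
    anova_p: Optional[float]
    tukey: Optional[pd.DataFrame]
    core_vs_cloud_p: Optional[float]


def evidence_by_occupancy(
    matrix: PangeneMatrix,
    evidence: pd.DataFrame,
    field: str,
    gene_filter: Optional[Callable[[str], bool]] = None,
) -> EvidenceComparison:
    """Summaries of an evidence covariate (aed / expression / plddt) by the
    occupancy of the parent pangene, over genes passing ``gene_filter``
    (typically a one-source restriction on the reference genome), with a
    one-way ANOVA and Tukey HSD across occupancy classes; the core-vs-cloud
    adjusted p-value is reported separately.
    """
    if field not in ("aed", "expression", "plddt"):
        raise ValueError(f"unknown evidence field {field!r}")
    values = evidence.set_index("gene_id")[field].dropna()
    n = matrix.panel_size
    rows = []
    for p in matrix.pangenes:
        occ = p.occupancy
        klass = classify_occupancy(occ, n).value
        for g in p.gene_ids():
            if gene_filter is not None and not gene_filter(g):
                continue
            if g in values.index:
                rows.append((occ, klass, values.loc[g]))
    df = pd.DataFrame(rows, columns=["occupancy", "occ_class", field])

    def summarize(group_col):
        agg = df.groupby(group_col)[field].agg(
            mean="mean",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            n="count",
        )
        agg["iqr"] = agg["q3"] - agg["q1"]
        return agg

    by_occ = summarize("occupancy")
    by_class = summarize("occ_class")

    anova_p = None
    tukey_df = None
    core_cloud = None
    groups = [
        grp[field].to_numpy()
        for _, grp in df.groupby("occ_class")
        if len(grp) >= 2
    ]
    if len(groups) >= 2 and df[field].nunique() == 1:
        # degenerate case: no variance anywhere, nothing to distinguish
        anova_p = 1.0
        core_cloud = 1.0 if {"core", "cloud"} <= set(df["occ_class"]) else None
    elif len(groups) >= 2:
        anova_p = float(stats.f_oneway(*groups).pvalue)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        usable = df.groupby("occ_class").filter(lambda s: len(s) >= 2)
        res = pairwise_tukeyhsd(usable[field], usable["occ_class"])
        tukey_df = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        mask = (
            tukey_df[["group1", "group2"]]
            .apply(frozenset, axis=1)
            .eq(frozenset({"core", "cloud"}))
        )
        if mask.any():
            core_cloud = float(tukey_df.loc[mask, "p-adj"].iloc[0])
    else:
        warnings.warn(f"{field}: fewer than two classes with >=2 values; test skipped")
    return EvidenceComparison(
        field=field,
        by_occupancy=by_occ,
        by_class=by_class,
        anova_p=anova_p,
        tukey=tukey_df,
        core_vs_cloud_p=core_cloud,
    )
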