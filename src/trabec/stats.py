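"""Phylogenetically informed allometry and lifestyle statistics.

Traits are analysed on the natural-log scale against the log VOI edge
length ``vl`` (the body-size proxy).  Regressions are generalized least
squares with a Brownian-motion covariance between species, optionally
rescaled by Pagel's lambda (estimated by maximum likelihood over [0, 1]).
Allometry is classified by testing the observed scaling exponent against
the exponent expected under isometry via a baseline shift: subtracting
``a_iso * log(vl)`` from the response turns the isometric null into a
zero-slope null.  Lifestyle contrasts are pairwise GLS fits with ``log vl``
as covariate, corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LIFESTYLES",
    "TRAIT_DIMENSIONS",
    "PGLSFit",
    "AllometryResult",
    "PairwiseLifestyleResult",
    "isometric_exponent",
    "phylo_covariance",
    "pgls_fit",
    "allometry_test",
    "lifestyle_pairwise",
    "bh_adjust",
    "validate_size_proxy",
    "allometry_table",
    "dataset_summary",
]

LIFESTYLES = ("arboreal", "fossorial", "semifossorial", "aerial")

#: physical length dimension of each trabecular parameter; under scaling
#: with constant trabecular geometry the isometric exponent equals the
#: dimension (BV/TV and DA are ratios, TbTh/TbSp lengths, BS/BV an inverse
#: length, ConnD an inverse volume)
TRAIT_DIMENSIONS = {"BVTV": 0, "DA": 0, "TbTh": 1, "TbSp": 1, "BSBV": -1, "ConnD": -3}

ALPHA = 0.05


@dataclass
class PGLSFit:
    """Coefficients and inference for one phylogenetic GLS fit."""

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    lam: float
    loglik: float
    n: int
    rsquared: float
    names: list[str] = field(default_factory=list)


@dataclass
class AllometryResult:
    """Observed vs isometric scaling for one trabecular parameter."""

    trait: str
    a_iso: float
    a_obs: float
    r_squared: float
    p_value: float
    classification: str  # "+allo" | "-allo" | "isometry"
    lam: float = math.nan


@dataclass
class PairwiseLifestyleResult:
    """Size-adjusted lifestyle contrast for one trait and lifestyle pair."""

    trait: str
    pair: tuple[str, str]
    coefficient: float
    p_raw: float
    p_adjusted: float = math.nan
    significant: bool = False
    lam: float = math.nan
    skipped_reason: str | None = None


def isometric_exponent(dimension: int) -> float:
    """Isometric scaling exponent of a trait against a linear size proxy.

    Under isometry (constant trabecular geometry) a trait of physical
    dimension length^d scales with vl^d, so the expected exponent is the
    dimension itself: 0 for the dimensionless BV/TV and DA, 1 for TbTh and
    TbSp, -1 for BS/BV and -3 for ConnD.
    """
    if dimension not in (-3, -1, 0, 1):
        raise ValueError(
            f"unknown trait dimension {dimension}; trabecular parameters have d in (-3, -1, 0, 1)"
        )
    return float(dimension)


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def phylo_covariance(
    tree: dendropy.Tree, lam: float = 1.0, taxa: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion species covariance, lambda-rescaled off-diagonals.

    ``V[i, j]`` is the root-to-MRCA shared path length of tips i and j
    (their common evolutionary history); the diagonal holds root-to-tip
    distances.  Pagel's lambda multiplies the off-diagonal entries only.
    Returns the matrix and the tip order used.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch lengths are not allowed")
    labels = _tip_labels(tree)
    if taxa is None:
        taxa = labels
    else:
        missing = set(taxa) - set(labels)
        if missing:
            raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    index = {lab: i for i, lab in enumerate(taxa)}
    n = len(taxa)
    V = np.zeros((n, n))
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            idx = index.get(node.taxon.label)
            tipsets[id(node)] = [] if idx is None else [idx]
            if idx is not None:
                V[idx, idx] = depth[id(node)]
            continue
        groups = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        V[i, j] = V[j, i] = lam * d
        tipsets[id(node)] = [i for g in groups for i in g]
    return V, list(taxa)


def pgls_fit(
    y: np.ndarray,
    X: np.ndarray,
    tree: dendropy.Tree | None,
    taxa: list[str],
    lam: float | str = "REML",
    names: list[str] | None = None,
    V0: np.ndarray | None = None,
) -> PGLSFit:
    """Generalized least squares under a (lambda-rescaled) Brownian covariance.

    ``lam`` is a fixed value in [0, 1], ``"REML"`` (default) or ``"ML"``:
    the likelihood criterion Pagel's lambda is profiled over, with
    coefficient inference conditional on the estimate.  REML is the
    default because it is far better calibrated for variance-structure
    parameters at comparative sample sizes (and is what the standard GLS
    tooling of the field defaults to).  With lambda = 0 the covariance is
    diagonal and the fit reduces to ordinary least squares.  Coefficient
    p-values use the t distribution with n - p degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations for {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        corr = np.corrcoef(X.T + 1e-300)
        bad = [
            f"{(names or list(range(p)))[i]}~{(names or list(range(p)))[j]}"
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 0.999999
        ]
        raise ValueError(f"singular design matrix; collinear columns: {bad or 'unknown'}")

    if V0 is None:
        V0, _ = phylo_covariance(tree, 1.0, taxa)
    diag = np.diag(np.diag(V0))

    def cov(l: float) -> np.ndarray:
        return l * V0 + (1 - l) * diag

    def negloglik(l: float, reml: bool) -> float:
        V = cov(l)
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        yw = solve_triangular(c, y, lower=True)
        Xw = solve_triangular(c, X, lower=True)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        if reml:
            sigma2 = float(resid @ resid) / (n - p)
            rdiag = np.linalg.qr(Xw, mode="r")
            logdet_xvx = 2.0 * float(np.sum(np.log(np.abs(np.diag(rdiag)))))
            return 0.5 * (
                (n - p) * math.log(2 * math.pi * sigma2) + (n - p) + logdet + logdet_xvx
            )
        sigma2 = float(resid @ resid) / n
        return 0.5 * (n * math.log(2 * math.pi * sigma2) + n + logdet)

    if lam in ("ML", "REML"):
        reml = lam == "REML"
        res = minimize_scalar(lambda l: negloglik(l, reml), bounds=(0.0, 1.0), method="bounded")
        lam_hat = float(res.x)
        # the bounded optimizer can stall off an endpoint; check both
        for cand in (0.0, 1.0):
            if negloglik(cand, reml) < negloglik(lam_hat, reml):
                lam_hat = cand
    else:
        lam_hat = float(lam)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    V = cov(lam_hat)
    fit = sm.GLS(y, X, sigma=V).fit()
    pvalues = np.asarray(fit.pvalues)
    # a numerically perfect fit leaves no residual variance to test against:
    # zero coefficients then carry no evidence (p = 1), nonzero ones are exact
    if fit.ssr <= 1e-12 * max(1.0, float(np.var(y) * n)):
        scale = max(1.0, float(np.max(np.abs(fit.params))))
        pvalues = np.where(np.abs(fit.params) <= 1e-8 * scale, 1.0, 0.0)
    return PGLSFit(
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues=pvalues,
        lam=lam_hat,
        loglik=-negloglik(lam_hat, lam == "REML"),
        n=n,
        rsquared=float(fit.rsquared),
        names=names or [f"x{i}" for i in range(p)],
    )


def _prune(tree: dendropy.Tree, taxa: list[str]) -> dendropy.Tree:
    sub = tree.extract_tree_with_taxa_labels(taxa)
    return sub


def allometry_test(
    df: pd.DataFrame,
    trait: str,
    tree: dendropy.Tree,
    a_iso: float | None = None,
    lam: float | str = "REML",
    alpha: float = ALPHA,
) -> AllometryResult:
    """Classify the scaling of one trait against vl.

    Fits ``log(trait) ~ log(vl)`` for the observed exponent and r^2, then
    refits the baseline-shifted response ``log(trait) - a_iso * log(vl)``
    (same covariance, lambda fixed at the first fit's estimate) to test the
    null that the observed exponent equals the isometric one.  The shifted
    slope equals ``a_obs - a_iso`` exactly.  p >= alpha is isometry,
    otherwise the sign of the deviation gives positive or negative
    allometry.
    """
    if a_iso is None:
        if trait not in TRAIT_DIMENSIONS:
            raise ValueError(f"no isometric exponent known for trait {trait!r}")
        a_iso = isometric_exponent(TRAIT_DIMENSIONS[trait])
    sub = _check_species(df, tree)
    taxa = list(sub["species"])
    if (sub[trait] <= 0).any() or (sub["vl"] <= 0).any():
        raise ValueError("traits and vl must be positive for the log transform")
    y = np.log(sub[trait].to_numpy(dtype=float))
    x = np.log(sub["vl"].to_numpy(dtype=float))
    X = np.column_stack([np.ones_like(x), x])
    ptree = _prune(tree, taxa)
    fit = pgls_fit(y, X, ptree, taxa, lam=lam, names=["intercept", "log_vl"])
    shifted = pgls_fit(
        y - a_iso * x, X, ptree, taxa, lam=fit.lam, names=["intercept", "log_vl"]
    )
    a_obs = float(fit.params[1])
    p = float(shifted.pvalues[1])
    if p >= alpha:
        cls = "isometry"
    else:
        cls = "+allo" if a_obs > a_iso else "-allo"
    return AllometryResult(
        trait=trait,
        a_iso=float(a_iso),
        a_obs=a_obs,
        r_squared=fit.rsquared,
        p_value=p,
        classification=cls,
        lam=fit.lam,
    )


def allometry_table(
    df: pd.DataFrame,
    tree: dendropy.Tree,
    traits: list[str] | None = None,
    lam: float | str = "REML",
) -> pd.DataFrame:
    """Allometry classification for every trabecular parameter."""
    traits = traits or list(TRAIT_DIMENSIONS)
    rows = []
    for t in traits:
        r = allometry_test(df, t, tree, lam=lam)
        rows.append(
            {
                "trait": t,
                "a_iso": r.a_iso,
                "a_obs": r.a_obs,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
                "classification": r.classification,
                "lambda": r.lam,
            }
        )
    return pd.DataFrame(rows)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lifestyle_pairwise(
    df: pd.DataFrame,
    trait: str,
    tree: dendropy.Tree,
    lam: float | str = "REML",
    alpha: float = ALPHA,
    min_per_group: int = 3,
) -> list[PairwiseLifestyleResult]:
    """Size-adjusted pairwise lifestyle contrasts for one trait.

    For each unordered lifestyle pair the data are subset to the two
    groups, the tree pruned accordingly, and ``log(trait) ~ log(vl) +
    lifestyle`` fit by PGLS; the indicator coefficient's p-value is the raw
    contrast p.  Benjamini-Hochberg correction is applied across the six
    pairs of this trait (the per-trait family); only the adjusted p-values
    are meant for reporting.  Pairs with fewer than ``min_per_group``
    species in either group are skipped with a reason.
    """
    sub_all = _check_species(df, tree)
    results: list[PairwiseLifestyleResult] = []
    tested: list[PairwiseLifestyleResult] = []
    for a, b in itertools.combinations(LIFESTYLES, 2):
        sub = sub_all[sub_all["lifestyle"].isin((a, b))]
        na = int((sub["lifestyle"] == a).sum())
        nb = int((sub["lifestyle"] == b).sum())
        if na < min_per_group or nb < min_per_group:
            results.append(
                PairwiseLifestyleResult(
                    trait=trait,
                    pair=(a, b),
                    coefficient=math.nan,
                    p_raw=math.nan,
                    skipped_reason=f"needs >= {min_per_group} species per group (got {na}, {nb})",
                )
            )
            continue
        taxa = list(sub["species"])
        y = np.log(sub[trait].to_numpy(dtype=float))
        x = np.log(sub["vl"].to_numpy(dtype=float))
        ind = (sub["lifestyle"] == b).to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x, ind])
        fit = pgls_fit(
            y, X, _prune(tree, taxa), taxa, lam=lam, names=["intercept", "log_vl", b]
        )
        r = PairwiseLifestyleResult(
            trait=trait,
            pair=(a, b),
            coefficient=float(fit.params[2]),
            p_raw=float(fit.pvalues[2]),
            lam=fit.lam,
        )
        results.append(r)
        tested.append(r)
    if tested:
        adj = bh_adjust([r.p_raw for r in tested])
        for r, q in zip(tested, adj):
            r.p_adjusted = float(q)
            r.significant = bool(q < alpha)
    return results


def lifestyle_pairwise_all(
    df: pd.DataFrame,
    tree: dendropy.Tree,
    traits: list[str] | None = None,
    lam: float | str = "REML",
    alpha: float = ALPHA,
    family: str = "per-trait",
) -> pd.DataFrame:
    """Pairwise lifestyle contrasts for all traits as a tidy table.

    ``family`` controls the multiple-testing scope: ``per-trait`` (default)
    corrects the six pairs within each trait separately; ``global`` pools
    every trait x pair test into one family.
    """
    if family not in ("per-trait", "global"):
        raise ValueError("family must be 'per-trait' or 'global'")
    traits = traits or list(TRAIT_DIMENSIONS)
    all_results: list[PairwiseLifestyleResult] = []
    for t in traits:
        all_results.extend(lifestyle_pairwise(df, t, tree, lam=lam, alpha=alpha))
    if family == "global":
        tested = [r for r in all_results if r.skipped_reason is None]
        if tested:
            adj = bh_adjust([r.p_raw for r in tested])
            for r, q in zip(tested, adj):
                r.p_adjusted = float(q)
                r.significant = bool(q < alpha)
    return pd.DataFrame(
        {
            "trait": [r.trait for r in all_results],
            "pair": ["-".join(r.pair) for r in all_results],
            "coefficient": [r.coefficient for r in all_results],
            "p_raw": [r.p_raw for r in all_results],
            "p_adjusted": [r.p_adjusted for r in all_results],
            "significant": [r.significant for r in all_results],
            "lambda": [r.lam for r in all_results],
            "skipped": [r.skipped_reason or "" for r in all_results],
        }
    )


def validate_size_proxy(
    df: pd.DataFrame,
    tree: dendropy.Tree,
    mass_column: str = "mass",
    lam: float | str = "REML",
) -> dict:
    """Check that vl scales isometrically with body mass (m ~ vl^3).

    Log-log regression of mass on vl; the deviation from exponent 3 is
    tested with the same baseline-shift device as the allometry tests.
    Requires mass for at least 10 species.
    """
    sub = df.dropna(subset=[mass_column])
    sub = _check_species(sub, tree)
    if len(sub) < 10:
        raise ValueError(f"need body mass for >= 10 species, got {len(sub)}")
    taxa = list(sub["species"])
    y = np.log(sub[mass_column].to_numpy(dtype=float))
    x = np.log(sub["vl"].to_numpy(dtype=float))
    X = np.column_stack([np.ones_like(x), x])
    ptree = _prune(tree, taxa)
    fit = pgls_fit(y, X, ptree, taxa, lam=lam, names=["intercept", "log_vl"])
    shifted = pgls_fit(y - 3.0 * x, X, ptree, taxa, lam=fit.lam)
    return {
        "exponent": float(fit.params[1]),
        "r_squared": fit.rsquared,
        "p_vs_isometry": float(shifted.pvalues[1]),
        "n": fit.n,
        "lambda": fit.lam,
    }


def _check_species(df: pd.DataFrame, tree: dendropy.Tree) -> pd.DataFrame:
    """Validate the trait table against the tree; returns the table."""
    if df["species"].duplicated().any():
        dups = sorted(df.loc[df["species"].duplicated(), "species"])
        raise ValueError(f"one row per species required; duplicated: {dups}")
    tips = set(_tip_labels(tree))
    orphans = sorted(set(df["species"]) - tips)
    if orphans:
        raise ValueError(f"species absent from the tree: {orphans}")
    return df


def dataset_summary(df: pd.DataFrame) -> dict:
    """Bookkeeping of a per-specimen trait table.

    Counts species, genera (first whitespace- or underscore-separated token
    of the species name) and species per lifestyle, and reports the DA
    extrema — the quantities usually quoted when describing a comparative
    dataset.
    """
    genera = df["species"].str.replace("_", " ").str.split().str[0]
    out = {
        "n_species": int(df["species"].nunique()),
        "n_genera": int(genera.nunique()),
        "lifestyle_counts": df.groupby("lifestyle")["species"].nunique().to_dict(),
    }
    if "DA" in df:
        out["da_min"] = float(df["DA"].min())
        out["da_max"] = float(df["DA"].max())
    return out
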