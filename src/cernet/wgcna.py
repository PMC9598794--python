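"""Weighted co-expression analysis, from scratch and deliberately small.

The workflow mirrors the classical recipe: soft-threshold the absolute
Pearson correlation (unsigned network, a_ij = |r_ij|^beta), pick beta as the
smallest power whose connectivity distribution fits a power law (signed
scale-free R^2 >= 0.85, with a documented fallback to beta = 21), build the
topological overlap matrix, cluster genes by average linkage on 1 - TOM with
a static cut, and summarize each module by its eigengene (first principal
component, sign-aligned with the module mean profile).  Module-trait
association is a plain Pearson correlation with a Student-t p-value; hub
genes are those with |kME| >= 0.8.

Not here on purpose: dynamic tree cut, module merging, signed networks,
block-wise computation for very large matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError

logger = logging.getLogger(__name__)

FALLBACK_BETA = 21
GREY = "grey"

#: Module labels by decreasing size, after the classical palette.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta",
)


@dataclass
class ModuleAssignment:
    """Gene->module map with eigengenes and per-gene kME."""

    modules: pd.Series  # gene -> module label ("grey" = unassigned)
    eigengenes: pd.DataFrame  # modules x samples, unit-norm rows
    kme: pd.Series  # gene -> correlation with its own module eigengene

    def module_sizes(self) -> pd.Series:
        return self.modules.value_counts()

    def genes_in(self, module: str) -> list[str]:
        return list(self.modules.index[self.modules == module])


@dataclass
class ModuleTraitAssociation:
    table: pd.DataFrame  # index module; columns r, p, significant

    def significant_modules(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


# ---------------------------------------------------------------------------
# scale-free fit and soft threshold
# ---------------------------------------------------------------------------

def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log regression of connectivity frequency on
    connectivity (quantile bins); negated when the slope is positive, so a
    genuinely scale-free (decreasing) distribution scores near +1."""
    k = np.asarray(k, dtype=float)
    if k.size < 20:
        raise ValidationError("need >= 20 genes for a scale-free fit")
    if np.any(k < 0):
        raise ValidationError("connectivities must be non-negative")
    if np.allclose(k, k[0]):
        raise ValidationError("all connectivities equal; fit undefined")
    # equal-width bins over the connectivity range (the classical fit index);
    # each bin contributes (mean k, observed frequency) to the log-log fit
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        log_k.append(np.log10(mk))
        log_f.append(np.log10(mask.mean()))
    if len(log_k) < 3:
        raise ValidationError("too few usable bins for a scale-free fit")
    fit = sps.linregress(log_k, log_f)
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def connectivity(adj: pd.DataFrame) -> np.ndarray:
    """Per-gene whole-network connectivity k_i = sum_{u != i} a_iu."""
    a = adj.to_numpy(dtype=float)
    return a.sum(axis=1) - np.diag(a)


def adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency |Pearson r|^beta, diagonal 1.

    ``expr`` is genes x samples (normalized values).
    """
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        flat = list(expr.index[sd == 0])
        raise ValidationError(f"zero-variance genes: {flat[:10]}")
    r = np.corrcoef(x)
    a = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def pick_soft_threshold(
    expr: pd.DataFrame,
    betas=range(1, 31),
    r2_target: float = 0.85,
    fallback: int = FALLBACK_BETA,
) -> tuple[int, pd.DataFrame]:
    """Smallest beta whose connectivity distribution reaches the scale-free
    fit target; falls back (with a warning) when no beta qualifies.

    Returns ``(beta, diagnostics)`` where the diagnostics table holds the
    signed R^2 and mean connectivity per candidate beta.
    """
    if expr.shape[0] < 20 or expr.shape[1] < 4:
        raise ValidationError("need >= 20 genes and >= 4 samples")
    rows = []
    chosen = None
    for b in betas:
        adj = adjacency(expr, b)
        k = connectivity(adj)
        try:
            r2 = scale_free_fit(k)
        except ValidationError:
            r2 = np.nan
        rows.append((b, r2, float(k.mean())))
        if chosen is None and np.isfinite(r2) and r2 >= r2_target:
            chosen = b
    diag = pd.DataFrame(rows, columns=["beta", "signed_r2", "mean_k"]).set_index("beta")
    if chosen is None:
        logger.warning(
            "no soft power in %s reached signed R^2 >= %.2f; falling back to %d",
            list(betas), r2_target, fallback,
        )
        chosen = fallback
    return chosen, diag


# ---------------------------------------------------------------------------
# topological overlap and modules
# ---------------------------------------------------------------------------

def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an unsigned adjacency.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    diagonal 1, clipped to [0, 1] for numerical safety.
    """
    a = adj.to_numpy(dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    # shared-neighbor term: (A @ A)_ij minus the u = i and u = j contributions
    shared = a @ a - np.diag(a)[:, None] * a - a * np.diag(a)[None, :]
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2.0
    excess = max(tom.max() - 1.0, -tom.min(), 0.0)
    if excess > 1e-9:
        logger.warning("TOM entries exceeded [0, 1] by %.3g before clipping", excess)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def cluster_modules(
    tom: pd.DataFrame,
    cut_height: float = 0.995,
    min_size: int = 30,
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters smaller than ``min_size`` are sent to "grey"; the rest are
    labelled by decreasing size with the classical color names.
    """
    genes = tom.index
    if len(genes) < 2:
        return pd.Series([GREY] * len(genes), index=genes, name="module")
    dist = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes.index[sizes >= min_size]
    # order kept clusters by decreasing size, ties broken by cluster id
    keep = sorted(keep, key=lambda c: (-sizes[c], c))
    name_of = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(keep)}
    out = labels.map(lambda c: name_of.get(c, GREY))
    out.name = "module"
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def module_eigengenes(expr: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized submatrix.

    Eigengenes are unit-norm per-sample vectors, sign-aligned so that the
    correlation with the module's mean expression profile is >= 0.  The grey
    (unassigned) set gets no eigengene.
    """
    out = {}
    for mod in sorted(set(modules) - {GREY}):
        genes = modules.index[modules == mod]
        x = _standardize(expr.loc[genes].to_numpy(dtype=float))
        if x.shape[0] == 1:
            v = x[0] / np.linalg.norm(x[0])
        else:
            _u, _s, vt = np.linalg.svd(x, full_matrices=False)
            v = vt[0]
        mean_profile = x.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        out[mod] = v
    eg = pd.DataFrame(out, index=expr.columns).T
    eg.index.name = "module"
    return eg


def compute_kme(expr: pd.DataFrame, modules: pd.Series,
                eigengenes: pd.DataFrame) -> pd.Series:
    """Correlation of each gene's profile with its own module's eigengene
    (NaN for grey genes)."""
    vals = {}
    x = expr.to_numpy(dtype=float)
    for i, g in enumerate(expr.index):
        mod = modules.loc[g]
        if mod == GREY or mod not in eigengenes.index:
            vals[g] = np.nan
            continue
        e = eigengenes.loc[mod].to_numpy(dtype=float)
        gi = x[i]
        if gi.std() == 0:
            vals[g] = np.nan
        else:
            vals[g] = float(np.corrcoef(gi, e)[0, 1])
    return pd.Series(vals, name="kME")


def assign_modules(
    expr: pd.DataFrame,
    beta: int | None = None,
    cut_height: float = 0.995,
    min_size: int = 30,
    r2_target: float = 0.85,
) -> ModuleAssignment:
    """Full module-detection pass: adjacency -> TOM -> clustering ->
    eigengenes -> kME.  ``beta=None`` triggers automatic soft-threshold
    selection."""
    if beta is None:
        beta, _diag = pick_soft_threshold(expr, r2_target=r2_target)
    adj = adjacency(expr, beta)
    tom = tom_similarity(adj)
    modules = cluster_modules(tom, cut_height=cut_height, min_size=min_size)
    eigengenes = module_eigengenes(expr, modules)
    kme = compute_kme(expr, modules, eigengenes)
    return ModuleAssignment(modules, eigengenes, kme)


# ---------------------------------------------------------------------------
# module-trait association and hubs
# ---------------------------------------------------------------------------

def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided Student-t p-value for a Pearson correlation,
    t = r sqrt(n-2) / sqrt(1-r^2), df = n - 2."""
    if n < 3:
        raise ValidationError("need >= 3 samples for a correlation p-value")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    trait,
    alpha: float = 0.05,
) -> ModuleTraitAssociation:
    """Pearson correlation of each module eigengene with a per-sample trait,
    with two-sided Student-t p-values (df = n - 2)."""
    trait = np.asarray(trait, dtype=float)
    if trait.size != eigengenes.shape[1]:
        raise ValidationError("trait length must match the sample count")
    if trait.std() == 0:
        raise ValidationError("constant trait; correlation undefined")
    n = trait.size
    rows = []
    for mod in eigengenes.index:
        e = eigengenes.loc[mod].to_numpy(dtype=float)
        r = float(np.corrcoef(e, trait)[0, 1])
        p = correlation_pvalue(r, n)
        rows.append((mod, r, p, p < alpha))
    table = pd.DataFrame(rows, columns=["module", "r", "p", "significant"])
    return ModuleTraitAssociation(table.set_index("module"))


def hub_genes(assignment: ModuleAssignment,
              kme_cutoff: float = 0.8) -> dict[str, set[str]]:
    """Per-module hub sets: genes with |kME| >= cutoff in their own module."""
    hubs: dict[str, set[str]] = {}
    for mod in assignment.eigengenes.index:
        genes = assignment.genes_in(mod)
        hubs[mod] = {
            g for g in genes
            if np.isfinite(assignment.kme.loc[g])
            and abs(assignment.kme.loc[g]) >= kme_cutoff
        }
    return hubs
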