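"""Windowed Poisson-regression insertion model (PRIM) and enrichment tests.

The genome is tiled into nonoverlapping windows (20 kb by default); each
window carries its TA-dinucleotide count and its observed number of unique
insertions.  A Poisson generalized linear model with log link,

    log E[insertions_w] = intercept + chromosome_effect(w) + beta * log(TA_w),

is fitted by iteratively reweighted least squares (IRLS); the fitted mean
of each window is the expected insertion count, compared with the observed
count through a one-sided upper-tail Poisson probability, with Bonferroni
correction over the tested windows.  Windows with zero TA sites cannot
receive TA-targeted insertions and are excluded from fitting and testing.

A randomized-null comparison (random TA-containing reference fragments,
mapped back to the genome) and a per-window occupancy histogram complete
the analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import ReferenceGenome, find_ta_positions

logger = logging.getLogger(__name__)

__all__ = [
    "WindowRecord",
    "PrimFit",
    "DegenerateFitError",
    "index_ta_sites",
    "build_windows",
    "assign_observed",
    "fit_prim",
    "poisson_upper_tail",
    "test_windows",
    "compare_random_null",
    "occupancy_histogram",
    "NullComparison",
]

WINDOW_COLUMNS = [
    "window_id", "chromosome", "start", "end", "ta_count",
    "observed_insertions", "short",
]

#: chromosome effect assigned when a chromosome has zero insertions
#: (complete separation); keeps expected counts defined instead of
#: letting IRLS diverge to -infinity
SEPARATION_CAP = -20.0


class DegenerateFitError(ValueError):
    """The model cannot be fitted (e.g. no observed insertions at all)."""


@dataclass
class WindowRecord:
    """One genomic window; ``start``/``end`` are 0-based half-open."""

    window_id: str
    chromosome: str
    start: int
    end: int
    ta_count: int
    observed_insertions: int = 0
    short: bool = False


@dataclass
class PrimFit:
    """Fitted PRIM coefficients and per-window expected counts.

    The first chromosome (in genome order) is the reference level with
    effect 0.  ``fitted`` is indexed by window_id over the tested
    (ta_count > 0) windows; at the optimum the intercept score equation
    forces sum(fitted) == sum(observed).
    """

    intercept: float
    chromosome_effects: dict[str, float]
    ta_coefficient: float
    fitted: pd.Series
    converged: bool
    iterations: int
    log_likelihood: float
    ta_coefficient_fixed: bool = False
    capped_chromosomes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Windowing


def index_ta_sites(genome: ReferenceGenome) -> dict[str, np.ndarray]:
    """Sorted 0-based positions of the T of every TA, per chromosome.

    Occurrences may overlap in the sense of "TATA" -> positions 0 and 2.
    """
    return {name: find_ta_positions(seq) for name, seq in genome.chromosomes.items()}


def build_windows(genome: ReferenceGenome, width: int = 20_000) -> pd.DataFrame:
    """Tile each chromosome from 0 in steps of ``width`` (default 20 kb).

    The final window of a chromosome may be short and is flagged; TA counts
    are filled from the TA index by binary range counting.
    """
    if width < 1000:
        raise ValueError("window width must be >= 1000 bp")
    ta_index = index_ta_sites(genome)
    rows = []
    wid = 0
    for name, seq in genome.chromosomes.items():
        length = len(seq)
        ta = ta_index[name]
        for start in range(0, length, width):
            end = min(start + width, length)
            wid += 1
            n_ta = int(
                np.searchsorted(ta, end, side="left")
                - np.searchsorted(ta, start, side="left")
            )
            rows.append(
                {
                    "window_id": f"w{wid:06d}",
                    "chromosome": name,
                    "start": start,
                    "end": end,
                    "ta_count": n_ta,
                    "observed_insertions": 0,
                    "short": end - start < width,
                }
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def assign_observed(windows: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Bucket each unique site into its window by T position (half-open:
    a site exactly on a boundary belongs to the right-hand window).

    Returns a copy of ``windows`` with observed_insertions filled; the
    total equals the site count.  A site outside every window indicates
    corrupt input and raises ValueError.
    """
    out = windows.copy()
    out["observed_insertions"] = 0
    counts: dict[tuple[str, int], int] = {}
    bychrom = {
        chrom: grp.sort_values("start")
        for chrom, grp in windows.groupby("chromosome", sort=False)
    }
    for row in sites.itertuples(index=False):
        grp = bychrom.get(row.chromosome)
        if grp is None:
            raise ValueError(f"site on unknown chromosome {row.chromosome!r}")
        starts = grp["start"].to_numpy()
        i = int(np.searchsorted(starts, row.position, side="right")) - 1
        if i < 0 or row.position >= int(grp["end"].iloc[i]):
            raise ValueError(
                f"site {row.chromosome}:{row.position} falls outside all windows"
            )
        key = (row.chromosome, i)
        counts[key] = counts.get(key, 0) + 1
    for (chrom, i), n in counts.items():
        out.loc[bychrom[chrom].index[i], "observed_insertions"] = n
    return out


# ---------------------------------------------------------------------------
# Poisson GLM via IRLS


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    from scipy.special import gammaln

    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def fit_prim(
    windows: pd.DataFrame,
    ta_coefficient: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> PrimFit:
    """Fit the Poisson regression insertion model by IRLS.

    ``ta_coefficient=None`` estimates the coefficient on log(TA count);
    passing a number (e.g. 0, or 1 for the TA-proportional null) fixes it
    as an offset.  Chromosomes with zero insertions are separated in the
    likelihood; their effects are capped at ``SEPARATION_CAP`` (with a
    warning) instead of diverging.  Convergence: relative log-likelihood
    change below ``tol`` or ``max_iter`` iterations.
    """
    tested = windows[windows["ta_count"] > 0]
    if len(tested) < 2:
        raise DegenerateFitError("need at least 2 windows with ta_count > 0")
    y = tested["observed_insertions"].to_numpy(dtype=float)
    if y.sum() <= 0:
        raise DegenerateFitError("no observed insertions; nothing to fit")
    log_ta = np.log(tested["ta_count"].to_numpy(dtype=float))
    chroms = list(dict.fromkeys(windows["chromosome"]))
    ref = chroms[0]

    # chromosomes with zero insertions among tested windows: complete
    # separation; fix their effect at the cap via the offset
    per_chrom = tested.groupby("chromosome", sort=False)["observed_insertions"].sum()
    capped = [c for c in chroms if c != ref and per_chrom.get(c, 0) == 0]
    if capped:
        logger.warning(
            "chromosome(s) %s have zero insertions; effect capped at %.0f",
            capped, SEPARATION_CAP,
        )
    free_chroms = [c for c in chroms[1:] if c not in capped]

    n = len(tested)
    cols: list[np.ndarray] = [np.ones(n)]
    for c in free_chroms:
        cols.append((tested["chromosome"] == c).to_numpy(dtype=float))
    offset = np.zeros(n)
    for c in capped:
        offset += SEPARATION_CAP * (tested["chromosome"] == c).to_numpy(dtype=float)
    fixed_ta = ta_coefficient is not None
    if fixed_ta:
        offset = offset + float(ta_coefficient) * log_ta
    else:
        cols.append(log_ta)
    X = np.column_stack(cols)
    p = X.shape[1]

    beta = np.zeros(p)
    beta[0] = np.log(y.mean() if y.mean() > 0 else 1e-8) - (
        float(ta_coefficient) * log_ta.mean() if fixed_ta else 0.0
    )
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -500, 30))
        ll = _poisson_loglik(y, np.maximum(mu, 1e-300))
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1e-12):
            converged = True
            break
        ll_old = ll
        # IRLS step: weighted least squares on the working response
        w = mu
        z = eta - offset + (y - mu) / np.maximum(mu, 1e-12)
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(np.sqrt(w)[:, None] * X,
                                   np.sqrt(w) * z, rcond=None)[0]
    eta = X @ beta + offset
    mu = np.exp(np.clip(eta, -500, 30))
    ll = _poisson_loglik(y, np.maximum(mu, 1e-300))

    effects = {ref: 0.0}
    for j, c in enumerate(free_chroms, start=1):
        effects[c] = float(beta[j])
    for c in capped:
        effects[c] = SEPARATION_CAP
    fit = PrimFit(
        intercept=float(beta[0]),
        chromosome_effects=effects,
        ta_coefficient=float(ta_coefficient) if fixed_ta else float(beta[-1]),
        fitted=pd.Series(mu, index=tested["window_id"].to_numpy(), name="expected"),
        converged=converged,
        iterations=it,
        log_likelihood=ll,
        ta_coefficient_fixed=fixed_ta,
        capped_chromosomes=capped,
    )
    resid = abs(float(mu.sum()) - float(y.sum())) / max(float(y.sum()), 1.0)
    if converged and resid > 1e-6:
        warnings.warn(
            f"intercept score equation violated (relative residual {resid:.2e})",
            RuntimeWarning,
        )
    return fit


# ---------------------------------------------------------------------------
# Tail probabilities and window tests


def poisson_upper_tail(k: int, mu: float) -> float:
    """P(Y >= k) for Y ~ Poisson(mu), survival-function formulation.

    Stable for k up to 1e6; k=0 returns exactly 1.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    k = int(k)
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return 1.0
    # regularized lower incomplete gamma: P(Y >= k) = P(k, mu)
    return float(stats.poisson.sf(k - 1, mu))


def test_windows(
    windows: pd.DataFrame,
    fit: PrimFit,
    alpha: float = 0.05,
    direction: str = "enrichment",
) -> pd.DataFrame:
    """One-sided per-window tests with Bonferroni correction.

    raw_p is the upper-tail Poisson probability of the observed count at
    the fitted mean ("enrichment"; "depletion" uses the lower tail);
    adjusted_p = min(1, m * raw_p) with m = number of tested windows.
    Windows with zero TA sites are reported with tested=False and no
    p-value.
    """
    if not fit.converged:
        raise ValueError("cannot test windows with an unconverged fit")
    out = windows.copy()
    out["expected"] = out["window_id"].map(fit.fitted)
    out["tested"] = out["ta_count"] > 0
    m = int(out["tested"].sum())
    raw = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        if not row.tested:
            continue
        if direction == "enrichment":
            raw[i] = poisson_upper_tail(row.observed_insertions, row.expected)
        elif direction == "depletion":
            raw[i] = float(stats.poisson.cdf(row.observed_insertions, row.expected))
        else:
            raise ValueError(f"unknown direction {direction!r}")
    out["raw_p"] = raw
    out["adjusted_p"] = np.minimum(1.0, m * out["raw_p"])
    out["enriched"] = out["adjusted_p"] < alpha
    out.loc[~out["tested"], "enriched"] = False
    return out


# ---------------------------------------------------------------------------
# Randomized-null comparison and occupancy


@dataclass
class NullComparison:
    """Observed vs randomized-null per-chromosome homogeneity."""

    per_chromosome: pd.DataFrame
    chi_square: float
    dof: int
    p_value: float
    overlay: pd.DataFrame


def compare_random_null(
    observed_sites: pd.DataFrame,
    random_sites: pd.DataFrame,
    windows: pd.DataFrame | None = None,
) -> NullComparison:
    """Compare real integrations with the randomized TA-fragment null.

    Per-chromosome count vectors for both site sets feed a chi-square
    homogeneity test; when a window table is supplied, a per-window
    occupancy overlay for both sets is attached for plotting.
    """
    if observed_sites is None or observed_sites.empty:
        raise ValueError("observed site table is empty")
    if random_sites is None or random_sites.empty:
        raise ValueError("random site table is empty")
    chroms = sorted(
        set(observed_sites["chromosome"]) | set(random_sites["chromosome"])
    )
    obs = observed_sites["chromosome"].value_counts()
    rnd = random_sites["chromosome"].value_counts()
    table = pd.DataFrame(
        {
            "chromosome": chroms,
            "observed": [int(obs.get(c, 0)) for c in chroms],
            "random": [int(rnd.get(c, 0)) for c in chroms],
        }
    )
    counts = table[["observed", "random"]].to_numpy().T
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    if counts.shape[1] < 2:
        chi2, p, dof = 0.0, 1.0, 0
    elif np.array_equal(counts[0] / counts[0].sum(), counts[1] / counts[1].sum()):
        # identical distributions: statistic is exactly 0
        chi2, p, dof = 0.0, 1.0, counts.shape[1] - 1
    else:
        chi2, p, dof, _ = stats.chi2_contingency(counts)
    overlay = pd.DataFrame()
    if windows is not None:
        w_obs = assign_observed(windows, observed_sites)
        w_rnd = assign_observed(windows, random_sites)
        overlay = w_obs[["window_id", "chromosome", "start", "end"]].copy()
        overlay["observed"] = w_obs["observed_insertions"].to_numpy()
        overlay["random"] = w_rnd["observed_insertions"].to_numpy()
    return NullComparison(
        per_chromosome=table,
        chi_square=float(chi2),
        dof=int(dof),
        p_value=float(p),
        overlay=overlay,
    )


def occupancy_histogram(windows: pd.DataFrame) -> dict[int, int]:
    """Complete histogram k -> number of windows with k insertions,
    including k = 0; satisfies sum_k k*count(k) = total insertions."""
    vc = windows["observed_insertions"].value_counts()
    kmax = int(windows["observed_insertions"].max()) if len(windows) else 0
    return {k: int(vc.get(k, 0)) for k in range(kmax + 1)}
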