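"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — direct scans, dense grid searches,
explicit series summation — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Sequence scanning


def naive_ta_scan(seq: str) -> list[int]:
    """Positions of the T of every TA by a per-position loop."""
    return [i for i in range(len(seq) - 1) if seq[i] == "T" and seq[i + 1] == "A"]


def naive_map(fragment: str, genome: dict[str, str]) -> list[tuple[str, int, str]]:
    """All exact occurrences of a fragment on either strand, by slice
    comparison at every position."""
    hits = []
    frc = rc(fragment)
    L = len(fragment)
    for name, seq in genome.items():
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            if window == fragment:
                hits.append((name, i, "+"))
            if window == frc:
                hits.append((name, i, "-"))
    return hits


# ---------------------------------------------------------------------------
# Restriction digestion / arc enumeration


def digest_oracle(seq: str, motif: str, offset: int) -> list[str]:
    """Linear digestion by explicit motif scan and split."""
    cuts = [
        i + offset
        for i in range(len(seq) - len(motif) + 1)
        if seq[i : i + len(motif)] == motif
    ]
    bounds = [0] + cuts + [len(seq)]
    return [seq[a:b] for a, b in zip(bounds, bounds[1:])]


def circle_occurrences(circle: str, needle: str) -> list[int]:
    """Occurrences of ``needle`` on a circle by per-rotation comparison."""
    L = len(circle)
    if len(needle) > L:
        return []
    doubled = circle + circle
    return [
        i for i in range(L) if doubled[i : i + len(needle)] == needle
    ]


def arc_products_oracle(circle: str, fwd_core: str, rev_core: str) -> list[str]:
    """All amplicons of a primer pair on a circle by exhaustive arc walks,
    considering both strands of the circle."""
    products = []
    rev_rc = rc(rev_core)
    for template in (circle, rc(circle)):
        f_hits = circle_occurrences(template, fwd_core)
        r_hits = circle_occurrences(template, rev_rc)
        L = len(template)
        doubled = template + template
        for f in f_hits:
            for r in r_hits:
                rend = r + len(rev_rc)
                arc = (rend - f) % L
                if arc == 0:
                    arc = L
                products.append(doubled[f : f + arc])
    return products


# ---------------------------------------------------------------------------
# Poisson tail and GLM grid search


def poisson_sf_series(k: int, mu: float) -> float:
    """P(Y >= k) by direct term-by-term summation of the Poisson pmf
    starting at k, with a stable upward recurrence."""
    if k == 0:
        return 1.0
    # log of the first term, then sum forward until negligible
    from math import exp, lgamma, log

    log_t = -mu + k * log(mu) - lgamma(k + 1)
    t = exp(log_t)
    total = 0.0
    j = k
    while t > 0.0:
        total += t
        j += 1
        t *= mu / j
        if j > mu and t < 1e-25 * total:
            break
    return min(total, 1.0)


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    from scipy.special import gammaln

    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def grid_fit_poisson(
    X: np.ndarray,
    y: np.ndarray,
    lo: float = -60.0,
    hi: float = 60.0,
    points: int = 9,
    target_half: float = 1e-7,
    max_passes: int = 400,
) -> tuple[np.ndarray, float]:
    """Maximum likelihood for a Poisson log-link model by iteratively
    refined dense grid search over all coefficients jointly.

    The search runs in the orthonormal basis of a QR decomposition of the
    design, where the log-likelihood contours are well conditioned, and
    maps the maximizer back; without this a narrow correlated ridge (e.g.
    intercept versus a covariate with little spread) traps an axis-aligned
    grid.  Each pass evaluates a full product grid centred on the
    incumbent; the window only shrinks while the incumbent is interior.
    """
    Q, R = np.linalg.qr(X)
    p = X.shape[1]
    center = np.zeros(p)
    half = (hi - lo) / 2.0
    best_gamma = center.copy()
    best_ll = -np.inf
    for _ in range(max_passes):
        axes = [np.linspace(c - half, c + half, points) for c in center]
        for combo in itertools.product(*axes):
            gamma = np.array(combo)
            mu = np.exp(np.clip(Q @ gamma, -700, 700))
            ll = poisson_loglik(y, np.maximum(mu, 1e-300))
            if ll > best_ll:
                best_ll = ll
                best_gamma = gamma
        step = 2 * half / (points - 1)
        on_edge = np.any(np.abs(best_gamma - center) > half - step / 2)
        center = best_gamma.copy()
        if not on_edge:
            half = 2 * step  # keep two old grid steps each side
        if half <= target_half:
            break
    beta = np.linalg.solve(R, best_gamma)
    return beta, best_ll


# ---------------------------------------------------------------------------
# Feature classification


def classify_brute(
    chromosome: str,
    position: int,
    genes,
    flank: int = 1000,
    precedence=("cds", "utr5", "utr3", "intron", "upstream_1kb",
                "downstream_1kb", "intergenic"),
) -> str:
    """Apply the precedence list to all (gene, interval) memberships,
    scanning every gene with explicit interval arithmetic."""
    memberships = set()
    for g in genes:
        if g.chromosome != chromosome:
            continue
        if g.start <= position < g.end:
            hit = None
            for s, e in g.cds:
                if s <= position < e:
                    hit = "cds"
            if hit is None:
                for s, e in g.utr5:
                    if s <= position < e:
                        hit = "utr5"
            if hit is None:
                for s, e in g.utr3:
                    if s <= position < e:
                        hit = "utr3"
            memberships.add(hit or "intron")
        else:
            if g.strand == "+":
                if g.start - flank <= position < g.start:
                    memberships.add("upstream_1kb")
                if g.end <= position < g.end + flank:
                    memberships.add("downstream_1kb")
            else:
                if g.end <= position < g.end + flank:
                    memberships.add("upstream_1kb")
                if g.start - flank <= position < g.start:
                    memberships.add("downstream_1kb")
    for cat in precedence:
        if cat in memberships:
            return cat
    return "intergenic"
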