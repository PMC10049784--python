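"""Crossover processes for a single meiotic product, and gamete formation.

Three crossover models are provided, all expressed on the genetic scale
(Morgans) along a chromosome of sex-specific genetic length L:

``poisson``
    No interference. The number of crossovers on the transmitted product is
    Poisson(L) and their locations are i.i.d. Uniform(0, L). This is the
    product-level view of a rate-2-per-Morgan chiasma process on the
    four-strand bundle thinned by 1/2 (no chromatid interference).

``count_location``
    Obligate chiasma. The bundle chiasma count is zero-truncated
    Poisson with untruncated mean 2L, chiasma locations are i.i.d.
    Uniform(0, L), and each chiasma lands on the sampled chromatid
    independently with probability 1/2. The product crossover count can
    still be 0, but every bundle has at least one chiasma.

``gamma``
    Crossover interference. Chiasmata on the bundle form a stationary
    renewal process with Gamma(shape nu, rate 2*nu per Morgan)
    inter-arrivals, so the bundle intensity is 2 per Morgan for every nu;
    the first event is drawn from the equilibrium (stationary excess)
    distribution, and each chiasma is thinned to the product with
    probability 1/2. nu = 1 reduces exactly to the Poisson model; nu > 1
    spreads crossovers apart (positive interference).

All three keep the expected product crossover intensity at 1 per Morgan
(the count-location model slightly exceeds L for short maps because of the
obligate chiasma: mean product count = L / (1 - exp(-2L))).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .haplotypes import Haplotype

__all__ = [
    "MeiosisModel",
    "MODEL_KINDS",
    "poisson_crossovers",
    "count_location_crossovers",
    "gamma_crossovers",
    "zero_truncated_poisson",
    "recombine",
]

MODEL_KINDS = ("poisson", "count_location", "gamma")


@dataclass(frozen=True)
class MeiosisModel:
    """Model choice plus sex-specific genetic lengths (Morgans)."""

    kind: str
    l_male: float
    l_female: float
    nu: float | None = None

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown meiosis model {self.kind!r}; choose from {MODEL_KINDS}")
        if self.l_male < 0 or self.l_female < 0:
            raise ValueError("genetic lengths must be >= 0")
        if self.kind == "gamma":
            if self.nu is None or self.nu <= 0:
                raise ValueError("gamma model requires interference shape nu > 0")
        elif self.nu is not None:
            raise ValueError(f"nu is only meaningful for the gamma model, not {self.kind!r}")

    def length_for(self, sex) -> float:
        # works with genealogy.Sex or the strings "male"/"female"
        name = getattr(sex, "name", str(sex)).lower()
        if name == "male":
            return self.l_male
        if name == "female":
            return self.l_female
        raise ValueError(f"unknown sex {sex!r}")

    def crossovers(self, sex, rng: np.random.Generator) -> np.ndarray:
        L = self.length_for(sex)
        if self.kind == "poisson":
            return poisson_crossovers(L, rng)
        if self.kind == "count_location":
            return count_location_crossovers(L, rng)
        return gamma_crossovers(L, self.nu, rng)


# ----------------------------------------------------------------------
# crossover location generators (genetic scale, Morgans)
# ----------------------------------------------------------------------

def poisson_crossovers(L: float, rng: np.random.Generator) -> np.ndarray:
    """Product crossovers under the no-interference model: count ~ Poisson(L),
    positions i.i.d. Uniform(0, L), returned sorted."""
    if L < 0:
        raise ValueError("genetic length must be >= 0")
    if L == 0:
        return np.empty(0)
    n = rng.poisson(L)
    return np.sort(rng.uniform(0.0, L, n))


def zero_truncated_poisson(lam: float, rng: np.random.Generator, size: int | None = None):
    """Sample N >= 1 with P(N=k) proportional to Poisson(lam) restricted to k >= 1.

    Scalar draws use rejection (exact); vectorized draws use quantile
    inversion (exact, different stream).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if size is None:
        while True:
            n = rng.poisson(lam)
            if n >= 1:
                return int(n)
    p0 = np.exp(-lam)
    u = rng.uniform(p0, 1.0, size)
    return stats.poisson.ppf(u, lam).astype(np.int64)


def count_location_crossovers(L: float, rng: np.random.Generator) -> np.ndarray:
    """Product crossovers under the obligate-chiasma count-location model."""
    if L <= 0:
        raise ValueError("count-location model requires genetic length > 0 (obligate chiasma)")
    n_bundle = zero_truncated_poisson(2.0 * L, rng)
    pos = rng.uniform(0.0, L, n_bundle)
    keep = rng.random(n_bundle) < 0.5
    return np.sort(pos[keep])


def _equilibrium_cdf(x: float, nu: float) -> float:
    """Stationary-excess CDF of the Gamma(nu, rate 2*nu) renewal process.

    F_e(x) = 2 x (1 - F_nu(x)) + F_{nu+1}(x), with F_k the CDF of
    Gamma(shape k, rate 2*nu); mean inter-arrival is 1/2 Morgan.
    """
    bx = 2.0 * nu * x
    return 2.0 * x * (1.0 - special.gammainc(nu, bx)) + special.gammainc(nu + 1.0, bx)


def _stationary_first_arrival(nu: float, rng: np.random.Generator) -> float:
    """Invert the equilibrium CDF by safeguarded Newton iteration (exact)."""
    u = rng.random()
    lo, hi = 0.0, 1.0
    while _equilibrium_cdf(hi, nu) < u:
        lo, hi = hi, hi * 2.0
    x = 0.5 * (lo + hi)
    for _ in range(100):
        f = _equilibrium_cdf(x, nu) - u
        if abs(f) < 1e-13:
            break
        if f > 0:
            hi = x
        else:
            lo = x
        d = 2.0 * (1.0 - special.gammainc(nu, 2.0 * nu * x))  # density f_e(x)
        step = x - f / d if d > 0 else None
        x = step if step is not None and lo < step < hi else 0.5 * (lo + hi)
    return x


def gamma_crossovers(L: float, nu: float, rng: np.random.Generator) -> np.ndarray:
    """Product crossovers under the stationary gamma renewal model."""
    if L <= 0:
        raise ValueError("gamma model requires genetic length > 0")
    if nu is None or nu <= 0:
        raise ValueError("interference shape nu must be > 0")
    scale = 1.0 / (2.0 * nu)  # Gamma(nu, rate 2*nu) inter-arrivals, mean 1/2
    events: list[float] = []
    t = _stationary_first_arrival(nu, rng)
    while t < L:
        events.append(t)
        t += rng.gamma(nu, scale)
    keep = rng.random(len(events)) < 0.5
    return np.asarray(events)[keep]


# ----------------------------------------------------------------------
# gamete formation
# ----------------------------------------------------------------------

def recombine(
    hap_a: Haplotype,
    hap_b: Haplotype,
    crossovers_bp: Sequence[int],
    start_with_a: bool = True,
) -> Haplotype:
    """Form the transmitted gamete from two parental haplotypes.

    The gamete copies ``hap_a`` (if ``start_with_a``) up to the first
    breakpoint, then alternates source at each subsequent breakpoint.
    Breakpoints are physical positions strictly inside (0, bp_len),
    strictly increasing. Adjacent equal-label output segments are merged,
    so a breakpoint inside a region where both parents carry the same
    founder chromosome leaves no trace (the mechanism behind concatenated
    descent of autozygous material).
    """
    if hap_a.bp_len != hap_b.bp_len:
        raise ValueError("parental haplotypes cover different chromosome lengths")
    bp_len = hap_a.bp_len
    prev = 0
    for x in crossovers_bp:
        if not prev < x < bp_len:
            raise ValueError(f"crossover {x} not strictly inside (0, {bp_len}) or unsorted")
        prev = x
    bounds = [0, *map(int, crossovers_bp), bp_len]
    src = (hap_a, hap_b) if start_with_a else (hap_b, hap_a)
    out_starts: list[int] = []
    out_labels: list[str] = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        h = src[k % 2]
        i = bisect_right(h.starts, lo) - 1
        while i < len(h.starts) and h.starts[i] < hi:
            seg_start = max(h.starts[i], lo)
            lab = h.labels[i]
            if not (out_labels and out_labels[-1] == lab):
                out_starts.append(seg_start)
                out_labels.append(lab)
            i += 1
    return Haplotype(tuple(out_starts), tuple(out_labels), bp_len)
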