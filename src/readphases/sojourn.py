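"""Parametric sojourn (state-occupancy) distributions for semi-Markov chains.

Occupancy times are counted in fixations and are at least 1, so the laws are
"shifted": ``1 + Binomial(n, p)`` and ``1 + NegativeBinomial(r, p)`` (number
of failures convention).  An ``absorbing`` law models a state that is never
left: its survival function is identically 1 and it has no finite parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betainc, gammaln

SHIFTED_BINOMIAL = "shifted_binomial"
SHIFTED_NEGATIVE_BINOMIAL = "shifted_negative_binomial"
ABSORBING = "absorbing"

_FAMILIES = (SHIFTED_BINOMIAL, SHIFTED_NEGATIVE_BINOMIAL, ABSORBING)


def _binom_logpmf(k: np.ndarray, n: int, p: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    out = np.full(k.shape, -np.inf)
    ok = (k >= 0) & (k <= n)
    kk = k[ok]
    with np.errstate(divide="ignore"):
        out[ok] = (
            gammaln(n + 1.0)
            - gammaln(kk + 1.0)
            - gammaln(n - kk + 1.0)
            + kk * math.log(p)
            + (n - kk) * math.log1p(-p)
        )
    return out


def _nbinom_logpmf(k: np.ndarray, r: float, p: float) -> np.ndarray:
    # number of failures before the r-th success
    k = np.asarray(k, dtype=float)
    out = np.full(k.shape, -np.inf)
    ok = k >= 0
    kk = k[ok]
    out[ok] = (
        gammaln(kk + r)
        - gammaln(r)
        - gammaln(kk + 1.0)
        + r * math.log(p)
        + kk * math.log1p(-p)
    )
    return out


@dataclass(frozen=True)
class SojournLaw:
    """Distribution of the number of consecutive fixations spent in a state.

    Parameters
    ----------
    family : str
        One of ``shifted_binomial`` (params ``(n, p)``),
        ``shifted_negative_binomial`` (params ``(r, p)``) or ``absorbing``
        (no parameters).
    params : tuple of float
        Family parameters; empty for the absorbing law.
    """

    family: str
    params: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown sojourn family: {self.family!r}")
        if self.family == ABSORBING:
            if self.params:
                raise ValueError("absorbing law has no parameters")
        else:
            if len(self.params) != 2:
                raise ValueError(f"{self.family} needs two parameters")
            a, p = self.params
            if not (0.0 < p < 1.0):
                raise ValueError("probability parameter must be in (0, 1)")
            if self.family == SHIFTED_BINOMIAL:
                if int(a) != a or a < 1:
                    raise ValueError("binomial size n must be a positive integer")
            elif a <= 0:
                raise ValueError("negative binomial r must be positive")

    # -- basic quantities ---------------------------------------------------
    @property
    def mean(self) -> float:
        """Expected occupancy in fixations (inf for the absorbing law)."""
        if self.family == ABSORBING:
            return math.inf
        a, p = self.params
        if self.family == SHIFTED_BINOMIAL:
            return 1.0 + a * p
        return 1.0 + a * (1.0 - p) / p

    def logpmf(self, d) -> np.ndarray:
        """log P(D = d) for occupancy d >= 1 (vectorized)."""
        d = np.asarray(d)
        if self.family == ABSORBING:
            return np.full(d.shape, -np.inf)
        a, p = self.params
        if self.family == SHIFTED_BINOMIAL:
            return _binom_logpmf(d - 1, int(a), p)
        return _nbinom_logpmf(d - 1, a, p)

    def pmf(self, d) -> np.ndarray:
        return np.exp(self.logpmf(d))

    def sf(self, d) -> np.ndarray:
        """Survival P(D >= d); equals 1 for every d for the absorbing law."""
        d = np.asarray(d, dtype=float)
        if self.family == ABSORBING:
            return np.ones(d.shape)
        a, p = self.params
        out = np.ones(d.shape)
        pos = d >= 2  # P(X >= k) with k = d - 1 >= 1 for the unshifted variable
        k = d[pos] - 1.0
        if self.family == SHIFTED_BINOMIAL:
            n = int(a)
            vals = np.zeros(k.shape)
            inside = k <= n
            ki = k[inside]
            # regularized incomplete beta: P(Bin(n,p) >= k) = I_p(k, n-k+1)
            vals[inside] = betainc(ki, n - ki + 1.0, p)
            out[pos] = vals
        else:
            # P(NB(r,p) >= k) = I_{1-p}(k, r)
            out[pos] = betainc(k, float(a), 1.0 - p)
        return out

    def logsf(self, d) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.sf(d))

    def entry_pmf(self, d_max: int) -> np.ndarray:
        """PMF over 1..d_max with the tail mass P(D >= d_max) lumped at d_max.

        This is the exact entry law for the countdown (remaining-duration)
        representation of a right-censored semi-Markov chain observed over at
        most ``d_max`` steps.
        """
        if self.family == ABSORBING:
            out = np.zeros(d_max)
            out[-1] = 1.0
            return out
        d = np.arange(1, d_max + 1)
        out = self.pmf(d)
        out[-1] = self.sf(np.array([float(d_max)]))[0]
        return out

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "SojournLaw":
        return cls(d["family"], tuple(d.get("params", ())))


def shifted_binomial(n: int, p: float) -> SojournLaw:
    return SojournLaw(SHIFTED_BINOMIAL, (int(n), float(p)))


def shifted_negative_binomial(r: float, p: float) -> SojournLaw:
    return SojournLaw(SHIFTED_NEGATIVE_BINOMIAL, (float(r), float(p)))


def absorbing() -> SojournLaw:
    return SojournLaw(ABSORBING)


def fit_sojourn_law(
    complete_weights: np.ndarray,
    censored_weights: np.ndarray,
    allow_absorbing: bool = True,
    families: str = "all",
    n_max_extra: int = 6,
) -> SojournLaw:
    """Weighted maximum likelihood over the supported families.

    Parameters
    ----------
    complete_weights : array (D,)
        Expected number of completed sojourns of duration ``d = 1..D``
        (contribute ``log pmf(d)``).
    censored_weights : array (D,)
        Expected number of right-censored sojourns of observed length ``v``
        (contribute ``log sf(v)``).
    allow_absorbing : bool
        The absorbing law is only admissible when essentially no completed
        sojourn mass is present; the caller additionally checks that the
        state has no outgoing transition mass.
    families : {"all", "nb"}
        ``"nb"`` restricts the search to the shifted negative binomial —
        cheaper, used during exploratory EM passes.
    """
    from scipy.optimize import minimize, minimize_scalar

    comp = np.asarray(complete_weights, dtype=float)
    cens = np.asarray(censored_weights, dtype=float)
    total = comp.sum() + cens.sum()
    if total <= 0:
        raise ValueError("no sojourn mass to fit")
    if allow_absorbing and comp.sum() < 1e-9 * max(total, 1.0):
        return SojournLaw(ABSORBING)

    D = comp.size
    d = np.arange(1, D + 1, dtype=float)
    # numerically negligible weights are dropped so that finite-support
    # families remain admissible
    floor = 1e-9 * total
    comp = np.where(comp > floor, comp, 0.0)
    cens = np.where(cens > floor, cens, 0.0)
    wsum = max(comp.sum() + cens.sum(), 1e-300)
    mean = (comp @ d + cens @ d) / wsum
    ex = max(mean - 1.0, 1e-3)
    var = comp @ (d - mean) ** 2 / max(comp.sum(), 1e-300) if comp.sum() > 0 else ex

    sel_c = comp > 0
    sel_z = cens > 0
    wc, kc = comp[sel_c], d[sel_c] - 1.0      # completed: unshifted counts
    wz, vz = cens[sel_z], d[sel_z]            # censored: observed lengths
    kz = vz - 1.0                             # sf argument
    zpos = kz >= 1.0                          # sf is 1 below that
    lgam_kc1 = gammaln(kc + 1.0) if wc.size else None

    def nb_nll(r: float, p: float) -> float:
        ll = 0.0
        if wc.size:
            lp = (gammaln(kc + r) - gammaln(r) - lgam_kc1
                  + r * math.log(p) + kc * math.log1p(-p))
            ll += wc @ lp
        if wz.size:
            sf = np.ones(kz.shape)
            sf[zpos] = betainc(kz[zpos], r, 1.0 - p)
            if np.any(sf <= 0.0):
                return np.inf
            ll += wz @ np.log(sf)
        return -ll

    def bin_nll(n: int, p: float) -> float:
        ll = 0.0
        if wc.size:
            if kc.max() > n:
                return np.inf
            lp = (gammaln(n + 1.0) - lgam_kc1 - gammaln(n - kc + 1.0)
                  + kc * math.log(p) + (n - kc) * math.log1p(-p))
            ll += wc @ lp
        if wz.size:
            if kz.max() > n:
                return np.inf
            sf = np.ones(kz.shape)
            sf[zpos] = betainc(kz[zpos], n - kz[zpos] + 1.0, p)
            if np.any(sf <= 0.0):
                return np.inf
            ll += wz @ np.log(sf)
        return -ll

    # shifted negative binomial: moment-matched start, Nelder-Mead polish
    p0 = min(max(ex / var, 1e-3), 1 - 1e-3) if var > ex else 0.5
    r0 = max(ex * p0 / max(1.0 - p0, 1e-6), 1e-2)

    def obj_nb(x):
        r = math.exp(min(max(x[0], -18.0), 12.0))
        q = 1.0 / (1.0 + math.exp(-x[1]))
        return nb_nll(r, min(max(q, 1e-9), 1 - 1e-9))

    x0 = np.array([math.log(r0), math.log(p0 / (1.0 - p0))])
    res = minimize(obj_nb, x0, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 250})
    r = math.exp(min(max(res.x[0], -18.0), 12.0))
    q = min(max(1.0 / (1.0 + math.exp(-res.x[1])), 1e-9), 1 - 1e-9)
    best_obj = res.fun
    best_law = SojournLaw(SHIFTED_NEGATIVE_BINOMIAL, (float(r), float(q)))

    if families == "all":
        # shifted binomial: small integer grid on n, 1-D optimization on p
        support_max = int(d[sel_c | sel_z].max())
        n_lo = max(1, support_max - 1)
        for n in range(n_lo, n_lo + n_max_extra):
            res = minimize_scalar(lambda q, n=n: bin_nll(n, q),
                                  bounds=(1e-6, 1 - 1e-6), method="bounded",
                                  options={"xatol": 1e-6})
            if res.fun < best_obj:
                best_obj = res.fun
                best_law = SojournLaw(SHIFTED_BINOMIAL, (n, float(res.x)))

    return best_law
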