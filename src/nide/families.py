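"""Normal/independent (N/I) error distributions.

An N/I random variable is a scale mixture of normals,

    Y = mu + e / sqrt(U),   e ~ N(0, sigma),   U ~ g(u; nu) on (0, inf),

so that ``Var(Y | U=u) = sigma / u`` and the marginal density is
``f(y) = int phi(y; mu, sigma/u) dG(u; nu)``.  Heavier-than-normal tails are
obtained whenever the mixing law puts mass below 1.  Five members are
supported:

=====================  ==========================================  =========
family                 mixing law g(u; nu)                         shape
=====================  ==========================================  =========
normal                 point mass at u = 1                         ()
t                      Gamma(v/2, rate v/2)                        (v,)
slash                  Beta(v, 1), i.e. v u^{v-1} on (0, 1)        (v,)
contaminated_normal    mass lambda at u = gamma, 1-lambda at u=1   (lam, gam)
laplace                1/U ~ Exp(rate v)                           (v,)
=====================  ==========================================  =========

``sigma`` denotes a *variance* throughout; the sampled precision is
``tau = 1/sigma``.  Gamma(a, b) is shape-rate (mean a/b).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from . import _kernels

__all__ = [
    "NIFamilySpec",
    "LocationScale",
    "FAMILIES",
    "mixing_density",
    "marginal_pdf",
    "sample_nid",
    "conditional_scale_draw",
]

FAMILIES = ("normal", "t", "slash", "contaminated_normal", "laplace")

#: integer codes shared with the numba kernels
FAMILY_CODES = {name: i for i, name in enumerate(FAMILIES)}

_ALIASES = {"cn": "contaminated_normal", "lap": "laplace", "gaussian": "normal",
            "student_t": "t", "sl": "slash", "n": "normal"}


@dataclass(frozen=True)
class NIFamilySpec:
    """Error-family tag plus its shape parameters.

    shape:
        t: (df,) with df > 0; slash: (v,) with v > 0;
        contaminated_normal: (lambda, gamma) each in (0, 1);
        laplace: (rate,) with rate > 0; normal: ().
    """

    family: str
    shape: tuple = field(default=())

    def __post_init__(self):
        fam = _ALIASES.get(self.family, self.family)
        object.__setattr__(self, "family", fam)
        object.__setattr__(self, "shape", tuple(float(s) for s in self.shape))
        if fam not in FAMILIES:
            raise ValueError(f"unknown N/I family {self.family!r}")
        s = self.shape
        if fam == "normal":
            if s:
                raise ValueError("normal family carries no shape parameter")
        elif fam == "contaminated_normal":
            if len(s) != 2 or not all(0.0 < x < 1.0 for x in s):
                raise ValueError("contaminated_normal needs (lambda, gamma) in (0,1)")
        else:
            if len(s) != 1 or s[0] <= 0.0:
                raise ValueError(f"{fam} needs one positive shape parameter")

    # -- convenience constructors -------------------------------------
    @classmethod
    def normal(cls) -> "NIFamilySpec":
        return cls("normal")

    @classmethod
    def t(cls, df: float) -> "NIFamilySpec":
        return cls("t", (df,))

    @classmethod
    def slash(cls, v: float) -> "NIFamilySpec":
        return cls("slash", (v,))

    @classmethod
    def contaminated_normal(cls, lam: float, gam: float) -> "NIFamilySpec":
        return cls("contaminated_normal", (lam, gam))

    @classmethod
    def laplace(cls, rate: float) -> "NIFamilySpec":
        return cls("laplace", (rate,))

    @property
    def code(self) -> int:
        return FAMILY_CODES[self.family]


@dataclass(frozen=True)
class LocationScale:
    """Location mu and conditional-variance scale sigma (Var(Y|u) = sigma/u)."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def tau(self) -> float:
        return 1.0 / self.sigma


def mixing_density(u, spec: NIFamilySpec):
    """Mixing density/mass g(u; nu) of the latent scale factor.

    For the two discrete families (normal, contaminated_normal) the
    probability *mass* at ``u`` is returned.  Vectorised over ``u``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0):
        raise ValueError("scale factor u must be positive")
    fam, s = spec.family, spec.shape
    if fam == "normal":
        return np.where(u == 1.0, 1.0, 0.0)
    if fam == "t":
        v = s[0]
        return stats.gamma.pdf(u, a=v / 2.0, scale=2.0 / v)
    if fam == "slash":
        v = s[0]
        return np.where(u < 1.0, v * u ** (v - 1.0), 0.0)
    if fam == "contaminated_normal":
        lam, gam = s
        out = np.zeros_like(u)
        out = np.where(u == gam, lam, out)
        out = np.where(u == 1.0, 1.0 - lam, out)
        return out
    # laplace: 1/U ~ Exp(v)  =>  g(u) = v u^{-2} exp(-v/u)
    v = s[0]
    return v * u ** -2.0 * np.exp(-v / u)


def marginal_pdf(y, loc: LocationScale, spec: NIFamilySpec):
    """Marginal N/I density f(y | mu, sigma, nu).

    Closed forms throughout: the slash integral reduces to a lower
    incomplete gamma function,
    f(y) = v / sqrt(2 pi sigma) * gamma(v + 1/2, a) / a^{v+1/2} with
    a = (y-mu)^2 / (2 sigma).
    """
    y = np.asarray(y, dtype=float)
    mu, sig = loc.mu, loc.sigma
    sd = np.sqrt(sig)
    fam, s = spec.family, spec.shape
    if fam == "normal":
        return stats.norm.pdf(y, mu, sd)
    if fam == "t":
        v = s[0]
        return stats.t.pdf((y - mu) / sd, v) / sd
    if fam == "contaminated_normal":
        lam, gam = s
        return lam * stats.norm.pdf(y, mu, np.sqrt(sig / gam)) + \
            (1.0 - lam) * stats.norm.pdf(y, mu, sd)
    if fam == "laplace":
        # variance mixing by Exp(v) gives a Laplace law with scale sqrt(sig/(2v))
        b = np.sqrt(sig / (2.0 * s[0]))
        return np.exp(-np.abs(y - mu) / b) / (2.0 * b)
    # slash: int_0^1 sqrt(u/(2 pi sig)) e^{-u a} v u^{v-1} du, a=(y-mu)^2/(2 sig)
    v = s[0]
    a = (y - mu) ** 2 / (2.0 * sig)
    c = v / np.sqrt(2.0 * np.pi * sig)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = c * special.gamma(v + 0.5) * special.gammainc(v + 0.5, a) \
            / a ** (v + 0.5)
    # a -> 0 limit: integral of u^{v-1/2} over (0,1)
    return np.where(a < 1e-12, c / (v + 0.5), val)[()]


def _sample_u(spec: NIFamilySpec, n: int, rng: np.random.Generator) -> np.ndarray:
    fam, s = spec.family, spec.shape
    if fam == "normal":
        return np.ones(n)
    if fam == "t":
        v = s[0]
        return rng.gamma(v / 2.0, 2.0 / v, size=n)
    if fam == "slash":
        return np.clip(rng.beta(s[0], 1.0, size=n), 1e-300, None)
    if fam == "contaminated_normal":
        lam, gam = s
        return np.where(rng.random(n) < lam, gam, 1.0)
    return s[0] / rng.exponential(1.0, size=n)  # laplace: u = v / Exp(1)


def sample_nid(loc: LocationScale, spec: NIFamilySpec, n: int,
               rng: np.random.Generator, return_u: bool = False):
    """Draw ``n`` i.i.d. variates from the marginal N/I distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = _sample_u(spec, n, rng)
    y = loc.mu + rng.standard_normal(n) * np.sqrt(loc.sigma / u)
    return (y, u) if return_u else y


def conditional_scale_draw(residual: float, tau: float, spec: NIFamilySpec,
                           rng: np.random.Generator, size: int | None = None):
    """Draw from the full conditional of the latent scale factor u.

    The kernel is ``u^{1/2} exp(-u tau residual^2 / 2) g(u; nu)``, the
    conditional of u given one centred observation with residual ``residual``
    and error precision ``tau``.  Draws are produced by the same compiled
    scalar kernels the Gibbs sweep uses.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    if spec.family == "normal":
        out = np.ones(1 if size is None else size)
        return float(out[0]) if size is None else out
    s1 = spec.shape[0]
    s2 = spec.shape[1] if len(spec.shape) > 1 else 0.0
    seed = int(rng.integers(2 ** 31 - 1))
    out = _kernels.scale_draws(spec.code, float(residual), float(tau),
                               s1, s2, 1 if size is None else int(size), seed)
    return float(out[0]) if size is None else out
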