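"""Substitution-model core.

Reversible 20-state amino-acid models are built from three interchangeable
parts: an exchangeability matrix (Poisson = all rates equal, or the
empirical LG matrix bundled as package data), one or more equilibrium
frequency profiles, and a discrete-gamma model of rate variation across
sites.  Three model flavours are provided:

* :class:`HomogeneousModel` — one profile for every site (e.g. LG+G4);
* :class:`MixtureModel` — a finite set of profiles with weights, shared
  across sites (the CXX family);
* :class:`SiteProfileModel` — one profile per alignment column (the PMSF
  construction, where the per-site profiles are posterior means under a
  fitted mixture).

The rate matrix follows the standard general-time-reversible construction
``Q_ij = s_ij * pi_j`` (i != j), scaled so the expected substitution rate at
stationarity is one.  Transition probabilities use the symmetrized
eigendecomposition ``B = D^{1/2} Q D^{-1/2}``, which is numerically stable
for reversible chains.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammainc, gammaincinv

from .alphabet import N_STATES

#: Floor applied to profile entries during regularization; keeps the chain ergodic.
PROFILE_FLOOR: float = 1e-10

_SUM_TOL = 1e-9


# ---------------------------------------------------------------------------
# Frequency profiles
# ---------------------------------------------------------------------------

class FrequencyProfile:
    """A 20-state amino-acid equilibrium/compositional frequency vector."""

    __slots__ = ("freqs",)

    def __init__(self, freqs: Sequence[float], *, regularize: bool = False):
        f = np.asarray(freqs, dtype=float)
        if f.shape != (N_STATES,):
            raise ValueError(f"profile must have exactly {N_STATES} entries, got {f.shape}")
        if (f < 0).any():
            raise ValueError("profile entries must be non-negative")
        if regularize:
            f = regularize_freqs(f)
        if abs(f.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"profile entries must sum to 1 (got {f.sum()!r})")
        self.freqs = f

    @classmethod
    def uniform(cls) -> "FrequencyProfile":
        return cls(np.full(N_STATES, 1.0 / N_STATES))

    def regularized(self) -> "FrequencyProfile":
        """Return a copy with zero entries floored at ``PROFILE_FLOOR`` and renormalized."""
        return FrequencyProfile(regularize_freqs(self.freqs))

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, FrequencyProfile) and np.array_equal(self.freqs, other.freqs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"FrequencyProfile({np.array2string(self.freqs, precision=3)})"


def regularize_freqs(freqs: np.ndarray) -> np.ndarray:
    """Floor entries at ``PROFILE_FLOOR`` and renormalize to sum 1."""
    f = np.maximum(np.asarray(freqs, dtype=float), PROFILE_FLOOR)
    return f / f.sum()


def regularize_profile_matrix(profiles: np.ndarray) -> np.ndarray:
    """Row-wise :func:`regularize_freqs` for an (n, 20) matrix."""
    p = np.maximum(np.asarray(profiles, dtype=float), PROFILE_FLOOR)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Exchangeabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExchangeabilityMatrix:
    """Symmetric relative-rate matrix with zero diagonal.

    ``name`` is one of ``Poisson`` (all off-diagonals equal), ``LG``
    (empirical, bundled) or ``GTR-custom``.
    """

    s: np.ndarray
    name: str = "GTR-custom"

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        if s.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.array_equal(s, s.T):
            raise ValueError("exchangeability matrix must be exactly symmetric")
        if np.diag(s).any():
            raise ValueError("exchangeability matrix must have a zero diagonal")
        off = s[~np.eye(N_STATES, dtype=bool)]
        if (off < 0).any():
            raise ValueError("exchangeabilities must be non-negative")
        object.__setattr__(self, "s", s)

    @classmethod
    def poisson(cls) -> "ExchangeabilityMatrix":
        s = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
        return cls(s, name="Poisson")

    @classmethod
    def lg(cls) -> "ExchangeabilityMatrix":
        s, _ = _load_lg()
        return cls(s, name="LG")


def lg_frequencies() -> FrequencyProfile:
    """The equilibrium amino-acid frequencies published with the LG matrix."""
    _, freqs = _load_lg()
    return FrequencyProfile(freqs / freqs.sum())


_LG_CACHE: dict = {}


def _load_lg():
    if "lg" not in _LG_CACHE:
        text = importlib.resources.files("hetcheck").joinpath("data/lg.txt").read_text()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        s = np.zeros((N_STATES, N_STATES))
        for i, line in enumerate(lines[: N_STATES - 1], start=1):
            row = [float(x) for x in line.split()]
            if len(row) != i:
                raise ValueError("malformed bundled LG matrix")
            s[i, :i] = row
        s = s + s.T
        freqs = np.array([float(x) for x in lines[N_STATES - 1].split()])
        _LG_CACHE["lg"] = (s, freqs)
    return _LG_CACHE["lg"]


# ---------------------------------------------------------------------------
# Discrete gamma rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaRateModel:
    """Discrete-gamma rates-across-sites model with K equiprobable categories."""

    alpha: float
    n_categories: int
    category_rates: np.ndarray
    category_weights: np.ndarray

    def __post_init__(self):
        rates = np.asarray(self.category_rates, dtype=float)
        weights = np.asarray(self.category_weights, dtype=float)
        if abs(float(weights @ rates) - 1.0) > _SUM_TOL:
            raise ValueError("weighted mean of category rates must be 1")
        if (np.diff(rates) <= 0).any() and len(rates) > 1:
            raise ValueError("category rates must be strictly increasing")
        object.__setattr__(self, "category_rates", rates)
        object.__setattr__(self, "category_weights", weights)


def discrete_gamma_rates(alpha: float, n_categories: int) -> GammaRateModel:
    """Discretize a mean-one gamma distribution into K equiprobable categories.

    Each category's rate is the conditional mean of the gamma density over
    its quantile bin (the mean-of-bins construction used by the major ML
    phylogenetics programs), so the weighted mean rate is exactly one.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    k = int(n_categories)
    if k == 1:
        return GammaRateModel(alpha, 1, np.array([1.0]), np.array([1.0]))
    # Gamma(shape=alpha, rate=alpha) has mean 1.  Bin boundaries are the
    # j/K quantiles; E[X | bin] = K * (F_{alpha+1}(b_hi) - F_{alpha+1}(b_lo))
    # where F_{alpha+1} is the CDF of Gamma(alpha+1, rate=alpha).
    probs = np.arange(1, k) / k
    bounds = gammaincinv(alpha, probs)  # boundaries of Gamma(alpha, 1), i.e. alpha * x
    upper = np.concatenate([gammainc(alpha + 1.0, bounds), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, bounds)])
    rates = k * (upper - lower)
    rates = rates / (rates.mean())  # exact unit mean despite rounding
    weights = np.full(k, 1.0 / k)
    return GammaRateModel(alpha, k, rates, weights)


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateMatrix:
    """Normalized reversible rate matrix together with its stationary profile."""

    Q: np.ndarray
    pi: FrequencyProfile


def build_rate_matrix(exch: ExchangeabilityMatrix, profile: FrequencyProfile) -> RateMatrix:
    """Assemble ``Q_ij = s_ij * pi_j`` scaled to one expected event per unit time.

    Profiles containing an exact zero are rejected: a zero equilibrium
    frequency makes the chain non-ergodic.  Call
    :meth:`FrequencyProfile.regularized` first if zeros are expected.
    """
    pi = profile.freqs
    if (pi <= 0).any():
        raise ValueError(
            "profile has a zero entry; regularize the profile before building a rate matrix"
        )
    Q = exch.s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(pi @ np.diag(Q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return RateMatrix(Q / mu, profile)


class SpectralDecomposition:
    """Eigendecomposition of a reversible rate matrix, cached for reuse.

    ``P(t) = left @ diag(exp(eigvals * t)) @ right`` with ``left = D^{-1/2} U``
    and ``right = U.T D^{1/2}`` for the symmetric ``B = D^{1/2} Q D^{-1/2}``.
    """

    __slots__ = ("eigvals", "left", "right")

    def __init__(self, rm: RateMatrix):
        pi = rm.pi.freqs
        d = np.sqrt(pi)
        B = d[:, None] * rm.Q / d[None, :]
        B = (B + B.T) / 2.0  # symmetrize away rounding
        w, U = np.linalg.eigh(B)
        self.eigvals = w
        self.left = U / d[:, None]
        self.right = U.T * d[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        P = (self.left * np.exp(self.eigvals * t)) @ self.right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_matrix(rm: RateMatrix, t: float) -> np.ndarray:
    """Transition probability matrix ``P(t) = expm(Q t)`` for branch length ``t >= 0``."""
    return SpectralDecomposition(rm).transition_matrix(t)


def batched_decompositions(profiles: np.ndarray, exch: ExchangeabilityMatrix):
    """Spectral decompositions for many profiles under one exchangeability matrix.

    Returns ``(eigvals (n,20), left (n,20,20), right (n,20,20))`` such that
    ``P_i(t) = left[i] @ diag(exp(eigvals[i] t)) @ right[i]``.  All rate
    matrices are normalized to unit expected rate, matching
    :func:`build_rate_matrix`.
    """
    pi = np.asarray(profiles, dtype=float)
    if (pi <= 0).any():
        raise ValueError("profiles must be regularized (strictly positive) for decomposition")
    n = pi.shape[0]
    Q = exch.s[None, :, :] * pi[:, None, :]
    idx = np.arange(N_STATES)
    Q[:, idx, idx] = 0.0
    diag = -Q.sum(axis=2)
    Q[:, idx, idx] = diag
    mu = -(pi * diag).sum(axis=1)
    Q /= mu[:, None, None]
    d = np.sqrt(pi)
    B = d[:, :, None] * Q / d[:, None, :]
    B = (B + np.transpose(B, (0, 2, 1))) / 2.0
    w, U = np.linalg.eigh(B)
    left = U / d[:, :, None]
    right = np.transpose(U, (0, 2, 1)) * d[:, None, :]
    assert left.shape == (n, N_STATES, N_STATES)
    return w, left, right


# ---------------------------------------------------------------------------
# Model flavours
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomogeneousModel:
    """One shared profile for all sites (e.g. LG+G4, Poisson+F+G4)."""

    exchangeabilities: ExchangeabilityMatrix
    profile: FrequencyProfile
    gamma: GammaRateModel

    @property
    def spec_string(self) -> str:
        return f"{self.exchangeabilities.name}+G{self.gamma.n_categories}"


@dataclass(frozen=True)
class MixtureModel:
    """Finite mixture of frequency profiles sharing one exchangeability matrix."""

    exchangeabilities: ExchangeabilityMatrix
    class_profiles: tuple
    class_weights: np.ndarray
    gamma: GammaRateModel

    def __post_init__(self):
        w = np.asarray(self.class_weights, dtype=float)
        if len(self.class_profiles) < 1:
            raise ValueError("mixture needs at least one class")
        if len(self.class_profiles) != len(w):
            raise ValueError("one weight per class profile required")
        if (w < 0).any() or abs(w.sum() - 1.0) > _SUM_TOL:
            raise ValueError("class weights must be non-negative and sum to 1")
        object.__setattr__(self, "class_profiles", tuple(self.class_profiles))
        object.__setattr__(self, "class_weights", w)

    @property
    def n_classes(self) -> int:
        return len(self.class_profiles)

    def profile_matrix(self) -> np.ndarray:
        return np.stack([p.freqs for p in self.class_profiles])

    @property
    def spec_string(self) -> str:
        return (
            f"{self.exchangeabilities.name}+C{self.n_classes}"
            f"+G{self.gamma.n_categories}"
        )


@dataclass(frozen=True)
class SiteProfileModel:
    """One frequency profile per alignment column (the PMSF construction)."""

    exchangeabilities: ExchangeabilityMatrix
    site_profiles: np.ndarray  # (n_sites, 20)
    gamma: GammaRateModel

    def __post_init__(self):
        p = np.asarray(self.site_profiles, dtype=float)
        if p.ndim != 2 or p.shape[1] != N_STATES:
            raise ValueError("site_profiles must be an (n_sites, 20) matrix")
        if (p < 0).any() or (np.abs(p.sum(axis=1) - 1.0) > _SUM_TOL).any():
            raise ValueError("every site profile must be a valid frequency vector")
        object.__setattr__(self, "site_profiles", p)

    @property
    def n_sites(self) -> int:
        return self.site_profiles.shape[0]

    @property
    def spec_string(self) -> str:
        return (
            f"PMSF({self.exchangeabilities.name},{self.n_sites} sites)"
            f"+G{self.gamma.n_categories}"
        )


Model = HomogeneousModel | MixtureModel | SiteProfileModel


# ---------------------------------------------------------------------------
# Model spec strings
# ---------------------------------------------------------------------------

_SPEC_RE = re.compile(
    r"^(?P<exch>LG|Poisson)"
    r"(?:\+C\[(?P<classes>[^\]]+)\])?"
    r"\+G(?P<k>\d+)$"
)
_PMSF_RE = re.compile(r"^PMSF:(?P<path>.+)\+G(?P<k>\d+)$")


def parse_model_spec(spec: str, *, alpha: float = 1.0) -> Model:
    """Build a model from a compact spec string.

    Supported forms::

        LG+G4                      homogeneous LG with its published frequencies
        Poisson+G4                 homogeneous Poisson, uniform frequencies
        Poisson+C[classes.tsv]+G4  finite mixture; class profiles and optional
                                   weights read from a profile file
        LG+C[classes.tsv]+G4       same with LG exchangeabilities
        PMSF:sites.sitefreq+G4     site-specific profiles from an IQ-TREE-style
                                   site-frequency file

    ``alpha`` is the gamma shape (the spec string fixes only the category
    count; the shape is a free, recorded parameter).
    """
    m = _PMSF_RE.match(spec)
    if m:
        from .likelihood import read_site_profiles

        samples = read_site_profiles(m.group("path"), dialect="iqtree_fs")
        profiles = samples[0]
        return SiteProfileModel(
            ExchangeabilityMatrix.poisson(),
            regularize_profile_matrix(profiles),
            discrete_gamma_rates(alpha, int(m.group("k"))),
        )
    m = _SPEC_RE.match(spec)
    if not m:
        raise ValueError(f"unrecognized model spec {spec!r}")
    gamma = discrete_gamma_rates(alpha, int(m.group("k")))
    if m.group("exch") == "LG":
        exch, profile = ExchangeabilityMatrix.lg(), lg_frequencies()
    else:
        exch, profile = ExchangeabilityMatrix.poisson(), FrequencyProfile.uniform()
    if m.group("classes") is None:
        return HomogeneousModel(exch, profile, gamma)
    from .likelihood import read_class_profiles

    profiles, weights = read_class_profiles(m.group("classes"))
    classes = [FrequencyProfile(regularize_freqs(p)) for p in profiles]
    return MixtureModel(exch, classes, weights, gamma)
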