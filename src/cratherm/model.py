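"""Equilibrium occupancy model of enhancer-driven RNAPII recruitment.

The system is a set of enhancer binding sites plus one promoter/RNAPII unit.
Each binding unit is either bound (1) or unbound (0); a system state is one
binary occupancy configuration.  The relative energy of a state sums per-unit
protein:DNA terms (``q``) and pairwise protein:protein terms (``omega``);
Boltzmann weights ``exp(-E/RT)`` over the admissible states give the
probability that RNAPII occupies the promoter in a given experimental
condition (Shea-Ackers formalism).

An experimental condition is the set of sites targeted by the synthetic
activator.  Untargeted sites are treated as inactive and their bound states
excluded from the partition sum.  In inhibition mode the convention flips:
targeted sites are silenced and the *untargeted* sites are active.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "SystemState",
    "ExperimentalState",
    "state_energy",
    "state_weight",
    "enumerate_states",
    "p_rnapii",
    "log_odds_rnapii",
    "state_design_matrix",
]

# kcal/mol conventions: R in kcal mol^-1 K^-1, 37 degrees C in kelvin.
GAS_CONSTANT_KCAL = 1.987204e-3
BODY_TEMPERATURE_K = 310.15

ACTIVATION = "activation"
INHIBITION = "inhibition"


@dataclass(frozen=True)
class ModelSpec:
    """Dimensions and thermodynamic constants of the model.

    Parameters
    ----------
    n_sites : int
        Number of enhancer binding sites (>= 1).  The full system has
        ``n_sites + 1`` binding units; the last unit is the promoter/RNAPII.
    temperature : float
        Temperature in kelvin (default 310.15 K, i.e. 37 C).
    gas_constant : float
        Gas constant in energy units per mol per kelvin (default kcal/mol/K),
        fixing the energy units of all ``q``/``omega`` parameters.
    """

    n_sites: int
    temperature: float = BODY_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.temperature <= 0 or self.gas_constant <= 0:
            raise ValueError("temperature and gas_constant must be positive")

    @property
    def n_units(self) -> int:
        """Total binding units: sites plus the promoter/RNAPII unit."""
        return self.n_sites + 1

    @property
    def rt(self) -> float:
        """Thermal energy R*T in the model's energy units."""
        return self.gas_constant * self.temperature

    @property
    def n_parameters(self) -> int:
        """Number of free energies: q per site, q promoter, site-site
        pairs, site-RNAPII terms (10 for three sites)."""
        n = self.n_sites
        return n + 1 + n * (n - 1) // 2 + n


@dataclass(eq=False)  # identity equality; compare via to_vector() for values
class ParameterSet:
    """The fitted relative energies, in the units fixed by :class:`ModelSpec`.

    Negative values are favourable, positive unfavourable, zero neutral.

    Attributes
    ----------
    q_site : ndarray, shape (n_sites,)
        Activator:DNA interaction per site.
    q_promoter : float
        RNAPII:promoter interaction.
    omega_site_site : ndarray, shape (n_sites, n_sites)
        Site-pair activator:activator interactions; only the upper triangle
        (i < j) is meaningful and the lower triangle/diagonal must be zero.
    omega_site_pol : ndarray, shape (n_sites,)
        Activator:RNAPII interaction per site.
    """

    q_site: np.ndarray
    q_promoter: float
    omega_site_site: np.ndarray
    omega_site_pol: np.ndarray

    def __post_init__(self) -> None:
        self.q_site = np.asarray(self.q_site, dtype=float)
        self.omega_site_site = np.asarray(self.omega_site_site, dtype=float)
        self.omega_site_pol = np.asarray(self.omega_site_pol, dtype=float)
        n = self.q_site.shape[0]
        if self.q_site.ndim != 1:
            raise ValueError("q_site must be a vector")
        if self.omega_site_pol.shape != (n,):
            raise ValueError(
                f"omega_site_pol has shape {self.omega_site_pol.shape}, expected ({n},)"
            )
        if self.omega_site_site.shape != (n, n):
            raise ValueError(
                f"omega_site_site has shape {self.omega_site_site.shape}, expected ({n}, {n})"
            )
        if np.any(np.tril(self.omega_site_site) != 0):
            raise ValueError("omega_site_site must be strictly upper triangular")
        for arr in (self.q_site, self.omega_site_site, self.omega_site_pol):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")
        if not np.isfinite(self.q_promoter):
            raise ValueError("q_promoter must be finite")

    @property
    def n_sites(self) -> int:
        return self.q_site.shape[0]

    # --- flat-vector view used by the optimizers -------------------------
    # layout: q_site (n), q_promoter, omega_site_site upper triangle in
    # (i, j) i<j lexicographic order, omega_site_pol (n).

    def to_vector(self) -> np.ndarray:
        n = self.n_sites
        iu = np.triu_indices(n, k=1)
        return np.concatenate(
            [self.q_site, [self.q_promoter], self.omega_site_site[iu], self.omega_site_pol]
        )

    @classmethod
    def from_vector(cls, theta: np.ndarray, n_sites: int) -> "ParameterSet":
        theta = np.asarray(theta, dtype=float)
        n = n_sites
        n_pairs = n * (n - 1) // 2
        expected = n + 1 + n_pairs + n
        if theta.shape != (expected,):
            raise ValueError(f"expected {expected} parameters for {n} sites, got {theta.shape}")
        q_site = theta[:n]
        q_promoter = float(theta[n])
        omega = np.zeros((n, n))
        omega[np.triu_indices(n, k=1)] = theta[n + 1 : n + 1 + n_pairs]
        omega_pol = theta[n + 1 + n_pairs :]
        return cls(q_site, q_promoter, omega, omega_pol)

    @classmethod
    def zeros(cls, n_sites: int) -> "ParameterSet":
        return cls.from_vector(np.zeros(n_sites + 1 + n_sites * (n_sites - 1) // 2 + n_sites), n_sites)

    def parameter_names(self) -> list[str]:
        """Names matching :meth:`to_vector` order (1-based site labels)."""
        n = self.n_sites
        names = [f"q_site{i + 1}" for i in range(n)]
        names.append("q_promoter")
        names += [f"omega_{i + 1},{j + 1}" for i in range(n) for j in range(i + 1, n)]
        names += [f"omega_pol{i + 1}" for i in range(n)]
        return names

    # --- JSON serialization ----------------------------------------------

    def to_dict(self) -> dict:
        iu = np.triu_indices(self.n_sites, k=1)
        return {
            "q_site": self.q_site.tolist(),
            "q_promoter": float(self.q_promoter),
            "omega_site_site": [
                [int(i), int(j), float(self.omega_site_site[i, j])]
                for i, j in zip(*iu)
            ],
            "omega_site_pol": self.omega_site_pol.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        q_site = np.asarray(d["q_site"], dtype=float)
        n = q_site.shape[0]
        omega = np.zeros((n, n))
        for i, j, v in d["omega_site_site"]:
            if not (0 <= i < j < n):
                raise ValueError(f"bad omega_site_site index ({i}, {j})")
            omega[i, j] = v
        return cls(q_site, float(d["q_promoter"]), omega, np.asarray(d["omega_site_pol"], dtype=float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SystemState:
    """One binary occupancy configuration of all units (promoter last)."""

    occupancy: tuple

    def __post_init__(self) -> None:
        if any(o not in (0, 1) for o in self.occupancy):
            raise ValueError("occupancy must be binary")

    @property
    def rnapii_bound(self) -> bool:
        return self.occupancy[-1] == 1


@dataclass(frozen=True)
class ExperimentalState:
    """Which sites are targeted by the synthetic effector, and in what mode.

    In activation mode the targeted sites are active (may be bound); in
    inhibition mode the targeted sites are silenced and the untargeted
    sites are active.  Inactive sites are pinned unbound; the promoter
    unit is never constrained.
    """

    targeted: frozenset = field(default_factory=frozenset)
    mode: str = ACTIVATION

    def __post_init__(self) -> None:
        object.__setattr__(self, "targeted", frozenset(int(i) for i in self.targeted))
        if self.mode not in (ACTIVATION, INHIBITION):
            raise ValueError(f"mode must be '{ACTIVATION}' or '{INHIBITION}', got {self.mode!r}")
        if any(i < 0 for i in self.targeted):
            raise ValueError("site indices must be nonnegative")

    def active_sites(self, n_sites: int) -> frozenset:
        if any(i >= n_sites for i in self.targeted):
            raise ValueError(f"targeted sites {sorted(self.targeted)} exceed n_sites={n_sites}")
        if self.mode == ACTIVATION:
            return self.targeted
        return frozenset(range(n_sites)) - self.targeted

    # --- text encoding used in tables ("1+3", "control") ------------------

    def to_label(self) -> str:
        if not self.targeted:
            return "control"
        return "+".join(str(i + 1) for i in sorted(self.targeted))

    @classmethod
    def from_label(cls, label: str, mode: str = ACTIVATION) -> "ExperimentalState":
        label = label.strip()
        if label.lower() in ("control", ""):
            return cls(frozenset(), mode)
        try:
            sites = frozenset(int(tok) - 1 for tok in label.split("+"))
        except ValueError as err:
            raise ValueError(f"cannot parse experimental-state label {label!r}") from err
        if any(i < 0 for i in sites):
            raise ValueError(f"site labels are 1-based; got {label!r}")
        return cls(sites, mode)


def state_energy(params: ParameterSet, state: SystemState) -> float:
    """Relative energy of one system state.

    Sums ``sigma_i * q_i`` over bound units plus ``sigma_i * sigma_j *
    omega_ij`` over bound pairs; pair terms involving the promoter unit use
    the site:RNAPII energies.  The empty state has energy zero.
    """
    occ = np.asarray(state.occupancy)
    n = params.n_sites
    if occ.shape != (n + 1,):
        raise ValueError(f"state has {occ.shape[0]} units, parameters expect {n + 1}")
    sites = occ[:n].astype(float)
    pol = float(occ[n])
    e = sites @ params.q_site + pol * params.q_promoter
    e += sites @ params.omega_site_site @ sites  # upper triangle only: each pair once
    e += pol * (sites @ params.omega_site_pol)
    return float(e)


def state_weight(params: ParameterSet, state: SystemState, spec: ModelSpec) -> float:
    """Boltzmann weight ``exp(-E/RT)`` of one system state."""
    return float(np.exp(-state_energy(params, state) / spec.rt))


def enumerate_states(spec: ModelSpec, exper: ExperimentalState) -> list[SystemState]:
    """All admissible system states for an experimental condition.

    Inactive sites are pinned to 0; active sites and the promoter unit take
    both values.  Ordering is lexicographic over the full occupancy vector,
    which is reproducible across runs.
    """
    active = sorted(exper.active_sites(spec.n_sites))
    free = active + [spec.n_sites]
    states = []
    for bits in itertools.product((0, 1), repeat=len(free)):
        occ = [0] * spec.n_units
        for pos, bit in zip(free, bits):
            occ[pos] = bit
        states.append(SystemState(tuple(occ)))
    return states


def _admissible_energies(params: ParameterSet, exper: ExperimentalState, spec: ModelSpec):
    states = enumerate_states(spec, exper)
    energies = np.array([state_energy(params, s) for s in states])
    bound = np.array([s.rnapii_bound for s in states])
    return energies, bound


def p_rnapii(params: ParameterSet, exper: ExperimentalState, spec: ModelSpec) -> float:
    """Probability that RNAPII occupies the promoter in condition ``exper``.

    Boltzmann-weighted fraction of admissible states with the promoter unit
    bound.  Computed in the log domain (log-sum-exp), so extreme energies do
    not overflow.
    """
    energies, bound = _admissible_energies(params, exper, spec)
    loga = -energies / spec.rt
    return float(np.exp(_logsumexp(loga[bound]) - _logsumexp(loga)))


def log_odds_rnapii(params: ParameterSet, exper: ExperimentalState, spec: ModelSpec) -> float:
    """Log odds ``log[P/(1-P)]`` of RNAPII occupancy in condition ``exper``.

    Computed as the difference of the bound- and unbound-state log
    partition sums, which keeps full precision even where ``1 - P``
    underflows; preferred over transforming :func:`p_rnapii` when odds are
    combined across conditions (the independence law).
    """
    energies, bound = _admissible_energies(params, exper, spec)
    loga = -energies / spec.rt
    return _logsumexp(loga[bound]) - _logsumexp(loga[~bound])


def _logsumexp(a: np.ndarray) -> float:
    m = np.max(a)
    return float(m + np.log(np.sum(np.exp(a - m))))


def state_design_matrix(spec: ModelSpec, exper: ExperimentalState) -> tuple[np.ndarray, np.ndarray]:
    """Linear map from the flat parameter vector to admissible-state energies.

    Returns ``(A, bound)`` where ``A @ theta`` gives the energy of every
    admissible state (rows in :func:`enumerate_states` order) and ``bound``
    flags the states with RNAPII at the promoter.  Used by the fitting code
    to evaluate the partition function as pure matrix arithmetic.
    """
    n = spec.n_sites
    iu_i, iu_j = np.triu_indices(n, k=1)
    states = enumerate_states(spec, exper)
    rows = []
    bound = []
    for s in states:
        occ = np.asarray(s.occupancy, dtype=float)
        sites, pol = occ[:n], occ[n]
        rows.append(
            np.concatenate([sites, [pol], sites[iu_i] * sites[iu_j], pol * sites])
        )
        bound.append(s.rnapii_bound)
    return np.array(rows), np.array(bound)
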