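"""Mass-action reaction networks for nitrocefin hydrolysis by metallo-β-lactamases.

Nitrocefin (S, 390 nm) is hydrolysed to a ring-opened product (P, 485 nm),
in some enzyme–metal combinations via a transient anionic intermediate
absorbing at 665 nm.  Two candidate mechanisms are modelled:

* **linear** — the intermediate is on-pathway::

      E + S  <=>[k1][k-1]  ES  ->[k2]  EI  ->[k3]  E + P

* **branched** — the enzyme–substrate complex partitions between a direct
  product channel and the intermediate channel::

      E + S  <=>[k1][k-1]  ES
      ES  ->[k2]  E + P          (direct channel)
      ES  ->[k3]  EI
      EI  ->[k4]  E + P

With this labelling, decay of the observable intermediate carries ``k3`` in
the linear scheme and ``k4`` in the branched scheme.  Product release
regenerates free enzyme, so substrate is fully consumed even at a 1:1
enzyme:substrate ratio.

Internal units are µM, seconds and cm throughout; second-order rate
constants are µM⁻¹·s⁻¹.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, IntegrationError

__all__ = [
    "Species",
    "Reaction",
    "ReactionScheme",
    "RateConstantSet",
    "ConcentrationTrajectory",
    "build_nitrocefin_scheme",
    "mass_action_rates",
    "integrate",
    "rate_limiting_step",
    "scheme_to_yaml",
    "scheme_from_yaml",
]

ROLE_ENZYME = "enzyme"
ROLE_SUBSTRATE = "substrate"
ROLE_ES_COMPLEX = "enzyme-substrate complex"
ROLE_EI_COMPLEX = "enzyme-intermediate complex"
ROLE_PRODUCT = "product"

_ROLES = {ROLE_ENZYME, ROLE_SUBSTRATE, ROLE_ES_COMPLEX, ROLE_EI_COMPLEX, ROLE_PRODUCT}


@dataclass(frozen=True)
class Species:
    """One chemical species of a scheme."""

    name: str
    role: str
    chromophoric: bool = False

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ConfigurationError(f"unknown species role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """A unimolecular or bimolecular mass-action step."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if not 1 <= len(self.reactants) <= 2:
            raise ConfigurationError(
                f"reaction {self.rate_label}: order must be 1 or 2, "
                f"got {len(self.reactants)} reactants"
            )
        if not self.products:
            raise ConfigurationError(f"reaction {self.rate_label}: no products")

    @property
    def order(self) -> int:
        return len(self.reactants)


@dataclass(frozen=True)
class ReactionScheme:
    """A validated mass-action network with enzyme/substrate conservation groups.

    ``enzyme_group`` lists every species containing the enzyme moiety and
    ``substrate_group`` every species derived from the substrate; each
    reaction must conserve both group totals, which pins total enzyme and
    total substrate-equivalents during any trajectory.
    """

    id: str
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    enzyme_group: tuple[str, ...]
    substrate_group: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "enzyme_group", tuple(self.enzyme_group))
        object.__setattr__(self, "substrate_group", tuple(self.substrate_group))

        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError("species names must be unique")
        for role in (ROLE_ENZYME, ROLE_SUBSTRATE, ROLE_PRODUCT):
            n = sum(1 for s in self.species if s.role == role)
            if n != 1:
                raise ConfigurationError(f"scheme must have exactly one {role!r} species, got {n}")
        known = set(names)
        for rxn in self.reactions:
            for name in (*rxn.reactants, *rxn.products):
                if name not in known:
                    raise ConfigurationError(
                        f"reaction {rxn.rate_label} references unknown species {name!r}"
                    )
        for group_name, group in (("enzyme", self.enzyme_group), ("substrate", self.substrate_group)):
            members = set(group)
            if not members <= known:
                raise ConfigurationError(f"{group_name} group references unknown species")
            for rxn in self.reactions:
                net = sum(1 for p in rxn.products if p in members) - sum(
                    1 for r in rxn.reactants if r in members
                )
                if net != 0:
                    raise ConfigurationError(
                        f"reaction {rxn.rate_label} does not conserve the {group_name} group"
                    )

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def rate_labels(self) -> tuple[str, ...]:
        return tuple(r.rate_label for r in self.reactions)

    def species_by_name(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def species_with_role(self, role: str) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.role == role)

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry, shape (n_species, n_reactions)."""
        n = np.zeros((len(self.species), len(self.reactions)))
        idx = {name: i for i, name in enumerate(self.species_names)}
        for j, rxn in enumerate(self.reactions):
            for r, count in Counter(rxn.reactants).items():
                n[idx[r], j] -= count
            for p, count in Counter(rxn.products).items():
                n[idx[p], j] += count
        return n


@dataclass(frozen=True)
class RateConstantSet:
    """Rate constants keyed by label: s⁻¹ for order 1, µM⁻¹·s⁻¹ for order 2."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        for label, value in self.values.items():
            if value < 0:
                raise ConfigurationError(f"rate constant {label} is negative ({value})")

    def __getitem__(self, label: str) -> float:
        return self.values[label]

    def require_for(self, scheme: ReactionScheme) -> None:
        missing = [lab for lab in scheme.rate_labels if lab not in self.values]
        if missing:
            raise ConfigurationError(
                f"rate constants missing for scheme {scheme.id!r}: {', '.join(missing)}"
            )

    def vector_for(self, scheme: ReactionScheme) -> np.ndarray:
        self.require_for(scheme)
        return np.array([self.values[lab] for lab in scheme.rate_labels])


@dataclass(frozen=True)
class ConcentrationTrajectory:
    """Species concentrations (µM) over a time grid (s), t[0] == 0."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_times, n_species)
    species: tuple[str, ...]
    scheme_id: str
    chromophoric: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_s, species, concentration_uM."""
        frames = [
            pd.DataFrame(
                {"time_s": self.times, "species": name, "concentration_uM": self[name]}
            )
            for name in self.species
        ]
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_nitrocefin_scheme(variant: str) -> ReactionScheme:
    """Build the linear or branched nitrocefin hydrolysis scheme.

    Parameters
    ----------
    variant : {"linear", "branched"}

    Returns
    -------
    ReactionScheme with species E, S, ES, EI, P and rate labels
    k1/k-1/k2/k3 (linear) or k1/k-1/k2/k3/k4 (branched).
    """
    species = (
        Species("E", ROLE_ENZYME),
        Species("S", ROLE_SUBSTRATE, chromophoric=True),
        Species("ES", ROLE_ES_COMPLEX, chromophoric=True),
        Species("EI", ROLE_EI_COMPLEX, chromophoric=True),
        Species("P", ROLE_PRODUCT, chromophoric=True),
    )
    binding = (
        Reaction(("E", "S"), ("ES",), "k1"),
        Reaction(("ES",), ("E", "S"), "k-1"),
    )
    if variant == "linear":
        reactions = binding + (
            Reaction(("ES",), ("EI",), "k2"),
            Reaction(("EI",), ("E", "P"), "k3"),
        )
    elif variant == "branched":
        reactions = binding + (
            Reaction(("ES",), ("E", "P"), "k2"),
            Reaction(("ES",), ("EI",), "k3"),
            Reaction(("EI",), ("E", "P"), "k4"),
        )
    else:
        raise ValueError(f"unknown scheme variant {variant!r}; expected 'linear' or 'branched'")
    return ReactionScheme(
        id=variant,
        species=species,
        reactions=reactions,
        enzyme_group=("E", "ES", "EI"),
        substrate_group=("S", "ES", "EI", "P"),
    )


def _rate_vector(scheme: ReactionScheme, kvec: np.ndarray, state: np.ndarray) -> np.ndarray:
    idx = {name: i for i, name in enumerate(scheme.species_names)}
    v = np.empty(len(scheme.reactions))
    for j, rxn in enumerate(scheme.reactions):
        term = kvec[j]
        for r in rxn.reactants:
            term = term * state[idx[r]]
        v[j] = term
    return v


def mass_action_rates(
    scheme: ReactionScheme, k: RateConstantSet, state: Mapping[str, float] | Sequence[float]
) -> np.ndarray:
    """Time derivatives (µM·s⁻¹) of every species under the law of mass action.

    ``state`` is either a mapping name → concentration or an array ordered
    like ``scheme.species_names``.
    """
    kvec = k.vector_for(scheme)
    if isinstance(state, Mapping):
        x = np.array([float(state.get(name, 0.0)) for name in scheme.species_names])
    else:
        x = np.asarray(state, dtype=float)
    return scheme.stoichiometry_matrix() @ _rate_vector(scheme, kvec, x)


def _make_rhs_jac(scheme: ReactionScheme, kvec: np.ndarray):
    """Closure-compiled RHS and Jacobian for solve_ivp."""
    n_sp = len(scheme.species)
    stoich = scheme.stoichiometry_matrix()
    idx = {name: i for i, name in enumerate(scheme.species_names)}
    reactant_idx = [tuple(idx[r] for r in rxn.reactants) for rxn in scheme.reactions]

    def rhs(t, x):
        v = np.empty(len(reactant_idx))
        for j, ridx in enumerate(reactant_idx):
            term = kvec[j]
            for i in ridx:
                term *= x[i]
            v[j] = term
        return stoich @ v

    def jac(t, x):
        dv = np.zeros((len(reactant_idx), n_sp))
        for j, ridx in enumerate(reactant_idx):
            if len(ridx) == 1:
                dv[j, ridx[0]] += kvec[j]
            else:  # bimolecular: product rule over the two reactants
                a, b = ridx
                dv[j, a] += kvec[j] * x[b]
                dv[j, b] += kvec[j] * x[a]
        return stoich @ dv

    return rhs, jac


def integrate(
    scheme: ReactionScheme,
    k: RateConstantSet,
    initial: Mapping[str, float] | Sequence[float],
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
) -> ConcentrationTrajectory:
    """Integrate the scheme's stiff mass-action ODEs on a fixed time grid.

    ``times`` must be strictly increasing and start at 0; ``initial`` maps
    species to non-negative µM concentrations (unlisted species start at 0
    when a mapping is given).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0 or t[0] != 0.0:
        raise ValueError("times must be a 1-D grid starting at 0")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if isinstance(initial, Mapping):
        unknown = set(initial) - set(scheme.species_names)
        if unknown:
            raise ConfigurationError(f"initial concentrations for unknown species: {unknown}")
        x0 = np.array([float(initial.get(name, 0.0)) for name in scheme.species_names])
    else:
        x0 = np.asarray(initial, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial concentrations must be non-negative")

    chromo = tuple(s.name for s in scheme.species if s.chromophoric)
    if t.size == 1:
        return ConcentrationTrajectory(t, x0[None, :].copy(), scheme.species_names, scheme.id, chromo)

    kvec = k.vector_for(scheme)
    rhs, jac = _make_rhs_jac(scheme, kvec)
    sol = solve_ivp(
        rhs, (0.0, t[-1]), x0, method=method, t_eval=t, rtol=rtol, atol=atol, jac=jac
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return ConcentrationTrajectory(t, sol.y.T.copy(), scheme.species_names, scheme.id, chromo)


def path_flux_fractions(scheme: ReactionScheme, k: RateConstantSet) -> dict[str, float]:
    """Fraction of substrate flux carried by each productive first-order step.

    Productive steps are first-order reactions that do not regenerate free
    substrate (reverse binding, e.g. ES → E + S, merely recycles and is
    excluded — on eventual conversion every molecule leaves through one of
    the productive channels).  At a branch point the flux divides in
    proportion to the competing productive rate constants; fractions
    propagate multiplicatively from the substrate to the product.
    """
    k.require_for(scheme)
    substrate = scheme.species_with_role(ROLE_SUBSTRATE)[0]
    productive: dict[str, list[Reaction]] = {}
    for rxn in scheme.reactions:
        if rxn.order == 1 and substrate not in rxn.products:
            productive.setdefault(rxn.reactants[0], []).append(rxn)

    reach: dict[str, float] = {substrate: 1.0}
    fractions: dict[str, float] = {}
    # breadth-first from the substrate; binding (bimolecular) carries full flux
    queue = [substrate]
    seen = {substrate}
    while queue:
        name = queue.pop(0)
        r = reach.get(name, 0.0)
        if name == substrate:
            for rxn in scheme.reactions:
                if rxn.order == 2 and substrate in rxn.reactants:
                    for prod in rxn.products:
                        if prod in scheme.substrate_group and prod not in seen:
                            reach[prod] = r
                            seen.add(prod)
                            queue.append(prod)
            continue
        out = productive.get(name, [])
        total = sum(k[rxn.rate_label] for rxn in out)
        for rxn in out:
            frac = r * (k[rxn.rate_label] / total) if total > 0 else 0.0
            fractions[rxn.rate_label] = fractions.get(rxn.rate_label, 0.0) + frac
            for prod in rxn.products:
                if prod in scheme.substrate_group and prod not in seen:
                    reach[prod] = reach.get(prod, 0.0) + frac
                    seen.add(prod)
                    queue.append(prod)
    return fractions


def rate_limiting_step(
    scheme: ReactionScheme, k: RateConstantSet, flux_threshold: float = 0.01
) -> str:
    """Label of the slowest productive first-order step on the substrate → product path.

    Steps carrying less than ``flux_threshold`` of the substrate flux are
    ignored — a parallel channel that is barely traversed cannot limit the
    overall rate — unless every step falls below it.  Ties resolve to the
    step appearing first in the scheme's reaction order.
    """
    fractions = path_flux_fractions(scheme, k)
    candidates = [
        rxn
        for rxn in scheme.reactions
        if rxn.rate_label in fractions and fractions[rxn.rate_label] >= flux_threshold
    ]
    if not candidates:
        candidates = [rxn for rxn in scheme.reactions if rxn.rate_label in fractions]
    return min(candidates, key=lambda rxn: k[rxn.rate_label]).rate_label


# ---------------------------------------------------------------------------
# YAML serialisation


def scheme_to_yaml(scheme: ReactionScheme, rates: RateConstantSet | None = None) -> str:
    doc: dict = {
        "id": scheme.id,
        "species": [
            {"name": s.name, "role": s.role, "chromophoric": s.chromophoric}
            for s in scheme.species
        ],
        "reactions": [
            {"reactants": list(r.reactants), "products": list(r.products), "rate_label": r.rate_label}
            for r in scheme.reactions
        ],
        "enzyme_group": list(scheme.enzyme_group),
        "substrate_group": list(scheme.substrate_group),
    }
    if rates is not None:
        doc["rates"] = {lab: float(v) for lab, v in rates.values.items()}
    return yaml.safe_dump(doc, sort_keys=False)


def scheme_from_yaml(text: str) -> tuple[ReactionScheme, RateConstantSet | None]:
    doc = yaml.safe_load(text)
    scheme = ReactionScheme(
        id=doc["id"],
        species=tuple(
            Species(s["name"], s["role"], bool(s.get("chromophoric", False)))
            for s in doc["species"]
        ),
        reactions=tuple(
            Reaction(tuple(r["reactants"]), tuple(r["products"]), r["rate_label"])
            for r in doc["reactions"]
        ),
        enzyme_group=tuple(doc["enzyme_group"]),
        substrate_group=tuple(doc["substrate_group"]),
    )
    rates = RateConstantSet(doc["rates"]) if "rates" in doc else None
    return scheme, rates
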