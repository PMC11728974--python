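"""Reaction network and cybernetic control laws for eicosanoid biosynthesis.

The model describes competition of arachidonic acid (AA) and
eicosapentaenoic acid (EPA) — or, in the alternative variant,
docosahexaenoic acid (DHA) — for the shared cyclooxygenase pool (eCOX) in
ATP-stimulated macrophages.  AA is converted to the 2-series prostaglandin
precursor PGH2 and EPA to the 3-series precursor PGH3 (DHA to the terminal
electrophilic oxo-derivative PD).  The two COX-catalysed conversions carry
cybernetic control variables:

* ``v_i`` (matching law) modulates enzyme *activity*:  v_i = rho_i / max_j rho_j
* ``u_i`` (proportion law) allocates enzyme *synthesis*: u_i = rho_i / sum_j rho_j

where ``rho_i = k_i * [eCOX] * [substrate_i]`` is the reaction flux.  The
controls encode the hypothesised cybernetic goal — maximising the combined
AA and EPA (or DHA) consumption rates — without requiring an explicit
mechanistic model of COX regulation.

Substrate fatty acids and ATP are measured inputs, not states: the ODE
state vector covers the nine (EPA variant) product metabolites plus four
enzyme pools, 13 equations in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "InducibleTerm",
    "EnzymeSynthesisSpec",
    "ReactionNetwork",
    "KineticParameters",
    "ControlVariables",
    "build_default_network",
    "count_parameters",
    "compute_fluxes",
    "cybernetic_controls",
    "metabolite_rhs",
    "enzyme_rhs",
    "assemble_rhs",
    "simplified_v",
    "switch_ratio",
]

#: the species whose instability precludes direct measurement
UNMEASURED_INTERMEDIATES = ("PGH2", "PGH3", "PD")


@dataclass(frozen=True)
class Species:
    """A chemical species in the network.

    ``role`` is one of ``input-substrate`` (measured model input, no ODE),
    ``metabolite`` or ``enzyme`` (one ODE each).  ``series`` tags the
    prostaglandin series: ``2-series`` (AA-derived, proinflammatory),
    ``3-series`` (EPA/DHA-derived, antiinflammatory) or ``none``.
    Metabolite concentrations are in pmol/ug DNA; enzyme levels are in
    arbitrary units (only the products k_i * [e] are identifiable).
    """

    id: str
    role: str
    measured: bool = False
    series: str = "none"

    def __post_init__(self) -> None:
        if self.role not in ("input-substrate", "metabolite", "enzyme"):
            raise ValueError(f"unknown species role {self.role!r}")
        if self.series not in ("2-series", "3-series", "none"):
            raise ValueError(f"unknown series tag {self.series!r}")


@dataclass(frozen=True)
class Reaction:
    """A single conversion ``substrate -> product``.

    ``enzyme`` is ``None`` for non-enzymatic first-order conversions.
    ``cybernetic`` marks the COX-catalysed substrate conversions that carry
    the (u, v) control pair; ``atp_modulated`` multiplies the rate by
    ``(1 + kATP*[ATP])`` to model the inducible COX2 response to the ATP
    danger signal.
    """

    substrate: str
    product: str
    enzyme: str | None
    rate_constant: str
    cybernetic: bool = False
    atp_modulated: bool = False

    def __post_init__(self) -> None:
        if self.atp_modulated and self.enzyme is None:
            raise ValueError(
                f"reaction {self.substrate}->{self.product}: "
                "ATP modulation requires an enzymatic reaction"
            )
        if self.cybernetic and self.enzyme != "eCOX":
            raise ValueError(
                f"reaction {self.substrate}->{self.product}: cybernetic "
                "control is reserved for the eCOX-catalysed conversions"
            )


@dataclass(frozen=True)
class InducibleTerm:
    """One Michaelis–Menten induction term in an enzyme balance.

    ``drivers`` are summed to form the inducing concentration S; the term
    contributes ``k_e * S / (Km + S)``, scaled by the synthesis control
    ``u`` when ``u_index`` is set (eCOX only).  ``k_e`` and ``km`` name
    entries of the parameter registry.
    """

    drivers: tuple[str, ...]
    k_e: str
    km: str
    u_index: int | None = None


@dataclass(frozen=True)
class EnzymeSynthesisSpec:
    """Constitutive + inducible synthesis and first-order decay of one enzyme.

    d[e]/dt = alpha + sum(inducible terms) - beta * [e]
    """

    enzyme: str
    alpha: str
    terms: tuple[InducibleTerm, ...]
    beta: str


@dataclass(frozen=True)
class ControlVariables:
    """Cybernetic control variables for the competing COX reactions."""

    u: np.ndarray
    v: np.ndarray


@dataclass
class ReactionNetwork:
    """The assembled reaction network for one model variant ("EPA" or "DHA")."""

    variant: str
    species: list[Species]
    reactions: list[Reaction]
    synthesis: list[EnzymeSynthesisSpec]
    degradation: dict[str, str]  # metabolite id -> degradation parameter name
    param_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(ids) != len(set(ids)):
            raise ValueError("species ids must be unique")
        self._index = {name: i for i, name in enumerate(self.state_names)}

    # -- structural views -------------------------------------------------
    @property
    def metabolites(self) -> list[str]:
        return [s.id for s in self.species if s.role == "metabolite"]

    @property
    def enzymes(self) -> list[str]:
        return [s.id for s in self.species if s.role == "enzyme"]

    @property
    def inputs(self) -> list[str]:
        return [s.id for s in self.species if s.role == "input-substrate"]

    @property
    def state_names(self) -> list[str]:
        return self.metabolites + self.enzymes

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def controlled(self) -> list[Reaction]:
        return [r for r in self.reactions if r.cybernetic]

    @property
    def measured_metabolites(self) -> list[str]:
        return [
            s.id for s in self.species if s.role == "metabolite" and s.measured
        ]

    def state_index(self, name: str) -> int:
        return self._index[name]


class KineticParameters(Mapping):
    """Named nonnegative kinetic constants, including the estimated initial
    enzyme levels ``X0_*`` (shared across experimental conditions)."""

    def __init__(self, values: Mapping[str, float]):
        vals = {str(k): float(v) for k, v in values.items()}
        for name, v in vals.items():
            if not math.isfinite(v):
                raise ValueError(f"parameter {name!r} is not finite")
            if v < 0:
                raise ValueError(f"parameter {name!r} is negative ({v})")
        self._values = vals

    def __getitem__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise KeyError(f"missing kinetic parameter {name!r}") from None

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def to_vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self[n] for n in names], dtype=float)

    @classmethod
    def from_vector(
        cls, names: Sequence[str], vector: np.ndarray
    ) -> "KineticParameters":
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (len(names),):
            raise ValueError("vector length does not match registry")
        # clip solver round-off: bounded optimizers may return -1e-17
        return cls(dict(zip(names, np.maximum(vector, 0.0))))

    def x0(self, network: ReactionNetwork) -> dict[str, float]:
        """Initial enzyme levels keyed by enzyme id."""
        return {e: self[f"X0_{e}"] for e in network.enzymes}

    def replace(self, **updates: float) -> "KineticParameters":
        new = dict(self._values)
        new.update(updates)
        return KineticParameters(new)

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"KineticParameters({len(self._values)} parameters)"


# ---------------------------------------------------------------------------
# network construction


def _register_params(network: ReactionNetwork) -> list[str]:
    """Enumerate the free-parameter registry in a stable order."""
    names: list[str] = []
    for r in network.reactions:
        names.append(r.rate_constant)
    for m, g in network.degradation.items():
        names.append(g)
    names += ["kATP", "dATP"]
    for spec in network.synthesis:
        names.append(spec.alpha)
        names.append(spec.beta)
        for term in spec.terms:
            names.append(term.k_e)
            names.append(term.km)
    for e in network.enzymes:
        names.append(f"X0_{e}")
    if len(names) != len(set(names)):
        raise ValueError("duplicate parameter names in registry")
    return names


def build_default_network(variant: str = "EPA") -> ReactionNetwork:
    """Assemble the default network for the requested model variant.

    The EPA variant pairs the AA->PGH2 branch with EPA->PGH3 and its
    downstream 3-series products (13 states).  The DHA variant replaces the
    3-series branch by the single terminal product PD.  The stable
    degradation product dhk-PGD2 is the one metabolite without a
    first-order loss term, which fixes the EPA-variant registry at 41 free
    parameters.
    """
    if variant not in ("EPA", "DHA"):
        raise ValueError(f"unknown model variant {variant!r}; use 'EPA' or 'DHA'")

    second = [  # AA branch, shared by both variants
        Species("AA", "input-substrate", measured=True, series="2-series"),
        Species("ATP", "input-substrate", measured=True),
        Species("PGH2", "metabolite", measured=False, series="2-series"),
        Species("PGD2", "metabolite", measured=True, series="2-series"),
        Species("PGE2", "metabolite", measured=True, series="2-series"),
        Species("dhkPGD2", "metabolite", measured=True, series="2-series"),
        Species("PGJ2", "metabolite", measured=True, series="2-series"),
        Species("dPGD2", "metabolite", measured=True, series="2-series"),
    ]
    aa_reactions = [
        Reaction("AA", "PGH2", "eCOX", "kPGH2", cybernetic=True, atp_modulated=True),
        Reaction("PGH2", "PGD2", "ePtgds", "kPGD2"),
        Reaction("PGH2", "PGE2", "ePtges", "kPGE2"),
        Reaction("PGD2", "dhkPGD2", "edhkPGD2", "k_dhkPGD2"),
        Reaction("PGD2", "PGJ2", None, "k_PGJ2"),
        Reaction("PGD2", "dPGD2", None, "k_15dPGD2"),
    ]
    enzymes = [
        Species("eCOX", "enzyme"),
        Species("ePtgds", "enzyme"),
        Species("ePtges", "enzyme"),
        Species("edhkPGD2", "enzyme"),
    ]

    if variant == "EPA":
        species = second + [
            Species("EPA", "input-substrate", measured=True, series="3-series"),
            Species("PGH3", "metabolite", measured=False, series="3-series"),
            Species("PGD3", "metabolite", measured=True, series="3-series"),
            Species("PGE3", "metabolite", measured=True, series="3-series"),
        ]
        reactions = aa_reactions + [
            Reaction("EPA", "PGH3", "eCOX", "kPGH3", cybernetic=True, atp_modulated=True),
            Reaction("PGH3", "PGD3", "ePtgds", "kPGD3"),
            Reaction("PGH3", "PGE3", "ePtges", "kPGE3"),
        ]
        cox_terms = (
            InducibleTerm(("AA",), "kePGH2", "KmAA", u_index=0),
            InducibleTerm(("EPA",), "kePGH3", "KmEPA", u_index=1),
        )
        ptg_drivers = ("PGH2", "PGH3")
    else:
        species = second + [
            Species("DHA", "input-substrate", measured=True, series="3-series"),
            Species("PD", "metabolite", measured=False, series="3-series"),
        ]
        reactions = aa_reactions + [
            Reaction("DHA", "PD", "eCOX", "kPD", cybernetic=True, atp_modulated=True),
        ]
        cox_terms = (
            InducibleTerm(("AA",), "kePGH2", "KmAA", u_index=0),
            InducibleTerm(("DHA",), "kePD", "KmDHA", u_index=1),
        )
        ptg_drivers = ("PGH2",)

    synthesis = [
        EnzymeSynthesisSpec("eCOX", "alpha_eCOX", cox_terms, "beta_eCOX"),
        EnzymeSynthesisSpec(
            "ePtgds",
            "alpha_ePtgds",
            (InducibleTerm(ptg_drivers, "ke_ePtgds", "Km_ePtgds"),),
            "beta_ePtgds",
        ),
        EnzymeSynthesisSpec(
            "ePtges",
            "alpha_ePtges",
            (InducibleTerm(ptg_drivers, "ke_ePtges", "Km_ePtges"),),
            "beta_ePtges",
        ),
        EnzymeSynthesisSpec(
            "edhkPGD2",
            "alpha_edhkPGD2",
            (InducibleTerm(("PGD2",), "ke_edhkPGD2", "Km_edhkPGD2"),),
            "beta_edhkPGD2",
        ),
    ]

    species = species + enzymes
    metabolites = [s.id for s in species if s.role == "metabolite"]
    # every metabolite except the stable end product dhk-PGD2 decays
    degradation = {
        m: ("g" + m) for m in metabolites if m != "dhkPGD2"
    }

    net = ReactionNetwork(
        variant=variant,
        species=species,
        reactions=reactions,
        synthesis=synthesis,
        degradation=degradation,
    )
    net.param_names = _register_params(net)
    return net


def count_parameters(network: ReactionNetwork) -> int:
    """Number of free parameters (rate/degradation/synthesis constants,
    ATP coupling and decay, and initial enzyme levels)."""
    return len(network.param_names)


# ---------------------------------------------------------------------------
# fluxes and control laws


def compute_fluxes(
    network: ReactionNetwork,
    state: Mapping[str, float],
    params: KineticParameters,
    substrates: Mapping[str, float],
) -> np.ndarray:
    """Fluxes rho_i = k_i * [eCOX] * [substrate_i] of the controlled reactions.

    The flux definition used by the control laws deliberately excludes the
    ATP modulation factor: ATP multiplies both competing rates equally and
    therefore cancels from every control ratio.
    """
    ecox = float(state["eCOX"])
    if ecox < 0:
        raise ValueError(f"negative eCOX concentration ({ecox})")
    out = np.empty(len(network.controlled))
    for i, rxn in enumerate(network.controlled):
        conc = float(substrates[rxn.substrate])
        if conc < 0:
            raise ValueError(
                f"negative {rxn.substrate} concentration ({conc})"
            )
        out[i] = params[rxn.rate_constant] * ecox * conc
    return out


def cybernetic_controls(fluxes: np.ndarray) -> ControlVariables:
    """Matching and proportion laws applied to a flux vector.

    v_i = rho_i / max_j rho_j, u_i = rho_i / sum_j rho_j.  When every flux
    is zero (e.g. at t=0 with no enzyme) the laws are indeterminate; the
    neutral convention u_i = 1/n, v_i = 1 reduces the model to unregulated
    mass action.
    """
    rho = np.asarray(fluxes, dtype=float)
    if np.any(rho < 0):
        raise ValueError("fluxes must be nonnegative")
    n = rho.size
    total = rho.sum()
    if total <= 0.0:
        return ControlVariables(u=np.full(n, 1.0 / n), v=np.ones(n))
    return ControlVariables(u=rho / total, v=rho / rho.max())


# ---------------------------------------------------------------------------
# rate balances


def _production_rate(
    rxn: Reaction,
    network: ReactionNetwork,
    state: Mapping[str, float],
    params: KineticParameters,
    substrates: Mapping[str, float],
    controls: ControlVariables,
) -> float:
    """Rate of the conversion described by ``rxn`` at the given state."""
    k = params[rxn.rate_constant]
    conc = (
        substrates[rxn.substrate]
        if rxn.substrate in substrates
        else state[rxn.substrate]
    )
    rate = k * conc
    if rxn.enzyme is not None:
        rate *= state[rxn.enzyme]
    if rxn.cybernetic:
        i = network.controlled.index(rxn)
        rate *= controls.v[i]
    if rxn.atp_modulated:
        rate *= 1.0 + params["kATP"] * substrates["ATP"]
    return rate


def metabolite_rhs(
    network: ReactionNetwork,
    state: Mapping[str, float],
    params: KineticParameters,
    substrates: Mapping[str, float],
    controls: ControlVariables,
) -> dict[str, float]:
    """Time derivatives of every metabolite: production minus first-order
    degradation minus downstream consumption.

    The COX-catalysed precursor balances carry the activity control v and
    the ATP factor, e.g.

        d[PGH2]/dt = v*kPGH2*[AA]*[eCOX]*(1+kATP*[ATP])
                     - gPGH2*[PGH2] - kPGD2*[PGH2]*[ePtgds]
                     - kPGE2*[PGH2]*[ePtges]

    Downstream conversions are plain mass action without control variables.
    """
    deriv = {m: 0.0 for m in network.metabolites}
    for rxn in network.reactions:
        rate = _production_rate(rxn, network, state, params, substrates, controls)
        deriv[rxn.product] += rate
        if rxn.substrate in deriv:
            deriv[rxn.substrate] -= rate
    for m, gname in network.degradation.items():
        deriv[m] -= params[gname] * state[m]
    return deriv


def enzyme_rhs(
    network: ReactionNetwork,
    state: Mapping[str, float],
    params: KineticParameters,
    substrates: Mapping[str, float],
    controls: ControlVariables,
) -> dict[str, float]:
    """Time derivatives of the enzyme pools.

    d[e]/dt = alpha + sum_terms [u *] k_e * S / (Km + S) - beta * [e]

    with the synthesis control u applied only to the eCOX induction terms.
    """
    deriv: dict[str, float] = {}
    for spec in network.synthesis:
        rate = params[spec.alpha]
        for term in spec.terms:
            s_val = 0.0
            for d in term.drivers:
                s_val += substrates[d] if d in substrates else state[d]
            km = params[term.km]
            if km == 0.0 and s_val == 0.0:
                raise ValueError(
                    f"enzyme {spec.enzyme}: Km={term.km} and driver are both "
                    "zero (indeterminate 0/0 induction term)"
                )
            mm = s_val / (km + s_val) if (km + s_val) > 0 else 1.0
            contribution = params[term.k_e] * mm
            if term.u_index is not None:
                contribution *= controls.u[term.u_index]
            rate += contribution
        rate -= params[spec.beta] * state[spec.enzyme]
        deriv[spec.enzyme] = rate
    return deriv


def assemble_rhs(
    t: float,
    y: np.ndarray,
    params: KineticParameters,
    network: ReactionNetwork,
    substrate_fn: Callable[[float], Mapping[str, float]],
    atp0: float,
) -> np.ndarray:
    """Full derivative vector at time ``t`` (minutes).

    Composes flux evaluation, the control laws and the metabolite/enzyme
    balances at the interpolated substrate concentrations.  ATP follows the
    fitted exponential decay [ATP](t) = ATP0 * exp(-dATP * t).  This is the
    readable reference path; :func:`cyberlipid.simulation.make_fast_rhs`
    provides an algebraically identical specialised closure for the solver
    hot loop.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite model state at t={t}: {y}")
    state = dict(zip(network.state_names, y))
    substrates = dict(substrate_fn(t))
    substrates["ATP"] = atp0 * math.exp(-params["dATP"] * t)
    # evaluate fluxes on concentrations clipped at zero: transient solver
    # undershoot must not feed negative values into the control ratios
    clipped_state = {k: max(v, 0.0) for k, v in state.items()}
    rho = compute_fluxes(network, clipped_state, params, substrates)
    controls = cybernetic_controls(rho)
    dm = metabolite_rhs(network, state, params, substrates, controls)
    de = enzyme_rhs(network, state, params, substrates, controls)
    return np.array(
        [dm[m] for m in network.metabolites] + [de[e] for e in network.enzymes]
    )


# ---------------------------------------------------------------------------
# analytical switch relations


def simplified_v(aa, epa, k_pgh2: float, k_pgh3: float):
    """Activity controls with the shared eCOX level cancelled analytically.

    v2 = kPGH2*[AA] / max(kPGH2*[AA], kPGH3*[EPA]) and symmetrically for
    v3; identical to the full matching-law v for any eCOX > 0.  Accepts
    scalars or broadcastable arrays.  Where both weighted concentrations
    are zero the degenerate convention (1, 1) applies.
    """
    aa = np.asarray(aa, dtype=float)
    epa = np.asarray(epa, dtype=float)
    if np.any(aa < 0) or np.any(epa < 0):
        raise ValueError("concentrations must be nonnegative")
    a = k_pgh2 * aa
    b = k_pgh3 * epa
    m = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        v2 = np.where(m > 0, a / np.where(m > 0, m, 1.0), 1.0)
        v3 = np.where(m > 0, b / np.where(m > 0, m, 1.0), 1.0)
    if v2.ndim == 0:
        return float(v2), float(v3)
    return v2, v3


def switch_ratio(k_pgh2: float, k_pgh3: float) -> float:
    """The [AA]:[EPA] concentration ratio at which activity dominance
    transfers between the 2-series and 3-series branches.

    At the switch locus kPGH2*[AA] = kPGH3*[EPA], hence
    [AA]switch/[EPA]switch = kPGH3/kPGH2.
    """
    if k_pgh2 <= 0:
        raise ValueError("kPGH2 must be positive to define the switch ratio")
    return k_pgh3 / k_pgh2
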