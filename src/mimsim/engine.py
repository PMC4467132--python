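"""ODE formulation, equilibration and time-course simulation.

The right-hand side assembles, per species, the signed sum of process
velocities: ``v = kon*prod(reactants) - koff*prod(products)`` for a
reversible reaction, ``v = kcat*[E]*[S]`` (mass action) or
``v = kcat*[E]*[S]/(Km+[S])`` (Michaelis-Menten) for catalysis.  Models
that carry a promoter configuration additionally drive their mRNA species
with the thermodynamic transcription rate (see :mod:`mimsim.promoter`).

Integration uses SciPy's implicit BDF method: signaling networks mix fast
binding (seconds) with slow transcription/degradation (hours), which makes
the system stiff.  The pre-treatment baseline is a quasi-stationary
equilibrium, operationalized as the first time the scaled derivative norm
``max_i |dx_i/dt| / (abs_tol + |x_i|)`` drops below a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkModel
from .promoter import (
    PromoterConfig,
    ccnd1_kdeg_modifier,
    p_rnap_bound,
    promoter_regulation_factor,
)

__all__ = [
    "SolverSettings",
    "SimulationContext",
    "SimulationResult",
    "EquilibrationResult",
    "EquilibrationError",
    "initialize_state",
    "build_rhs",
    "equilibrate",
    "simulate",
]


class EquilibrationError(RuntimeError):
    pass


@dataclass
class SolverSettings:
    rel_tol: float = 1e-8
    abs_tol: float = 1e-9  # nM
    t_max_equilibration: float = 2e7  # s
    equilibration_tol: float = 1e-10  # 1/s, scaled derivative norm
    max_step: float = np.inf  # s

    def __post_init__(self) -> None:
        for name in ("rel_tol", "abs_tol", "t_max_equilibration",
                     "equilibration_tol", "max_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SolverSettings.{name} must be positive")


@dataclass
class SimulationContext:
    """Switches that modulate the RHS for a particular virtual experiment.

    mek_inhibited engages the CCND1 destabilization term (the effective
    CCND1 kdeg is scaled by ERKPP_control / ERKPP(t), with ERKPP evaluated
    dynamically along the treated trajectory against the control reference
    level).  ``actd`` models Actinomycin D by zeroing mRNA synthesis; with
    ``actd_blocks_destabilization`` on (default), blocking transcription
    also switches the destabilization term off, reflecting its dependence
    on the transcription of an intermediary gene.
    """

    mek_inhibited: bool = False
    erkpp_control: float | None = None
    actd: bool = False
    actd_blocks_destabilization: bool = True
    freeze_mrna: bool = False
    erkpp_floor_fraction: float = 1e-6
    metadata: dict = field(default_factory=dict)
    # set by the RHS when the ERKPP floor engages; reported once by simulate()
    _erkpp_floor_hit: bool = field(default=False, repr=False, compare=False)

    def destabilization_active(self) -> bool:
        if not self.mek_inhibited:
            return False
        if self.actd and self.actd_blocks_destabilization:
            return False
        return True


@dataclass
class SimulationResult:
    """Trajectory on an output grid; concentrations clipped to >= 0 at output."""

    times: np.ndarray  # (T,)
    concentrations: np.ndarray  # (T, n_species)
    species_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {sid: i for i, sid in enumerate(self.species_ids)}

    def trajectory(self, species_id: str) -> np.ndarray:
        return self.concentrations[:, self._index[species_id]]

    def value(self, species_id: str, time: float) -> float:
        return float(np.interp(time, self.times, self.trajectory(species_id)))

    def state_at(self, time: float) -> dict[str, float]:
        return {sid: self.value(sid, time) for sid in self.species_ids}

    def to_frame(self):
        """Tidy (time, species, concentration) DataFrame."""
        import pandas as pd

        t = np.repeat(self.times, len(self.species_ids))
        sp = np.tile(np.array(self.species_ids, dtype=object), len(self.times))
        return pd.DataFrame(
            {"time": t, "species": sp, "concentration": self.concentrations.ravel()}
        )


@dataclass
class EquilibrationResult:
    state: np.ndarray
    time: float
    converged: bool
    derivative_norm: float


# ---------------------------------------------------------------------------


def initialize_state(
    model: NetworkModel,
    genotype: "object | None" = None,
) -> np.ndarray:
    """Pre-equilibration state: each moiety pool entirely in its unbound form.

    The total concentration of each basic protein (declared initial
    concentrations summed over all forms) is assigned wholly to the unbound
    basic species; modified forms and complexes start at zero; mRNA levels
    keep their declared values.  Concentration-type genotype directives
    (null, partial_loss, overexpression) are applied to the totals before
    integration; rate-type directives (constitutive activation) belong to
    :func:`mimsim.perturb.apply_genotype`.
    """
    from .network import moiety_totals

    totals = moiety_totals(model)
    if genotype is not None:
        from .perturb import scale_factors

        for moiety, factor in scale_factors(model, genotype).items():
            if moiety not in totals:
                raise KeyError(f"genotype directive targets unknown moiety {moiety!r}")
            totals[moiety] *= factor

    unbound: dict[str, str] = {}
    for s in model.species:
        if len(s.composition) == 1 and next(iter(s.composition.values())) == 1:
            m = next(iter(s.composition))
            if s.role in ("basic", "inhibitor") and m not in unbound:
                unbound[m] = s.id

    idx = model.species_index()
    y0 = np.zeros(len(model.species))
    for s in model.species:
        if s.role == "mRNA":
            y0[idx[s.id]] = s.initial_concentration
    for m, total in totals.items():
        if m not in unbound:
            raise ValueError(f"moiety {m!r} has no unbound basic species to hold its pool")
        y0[idx[unbound[m]]] = total
    return y0


def build_rhs(
    model: NetworkModel,
    context: SimulationContext | None = None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the model into a ``f(t, y) -> dy/dt`` callable."""
    ctx = context or SimulationContext()
    idx = model.species_index()
    n = len(model.species)

    rev = [
        (
            np.array([idx[s] for s in r.reactants]),
            np.array([idx[s] for s in r.products]),
            r.kon,
            r.koff,
        )
        for r in model.reversible
    ]
    cat = [
        (idx[c.enzyme], idx[c.substrate], idx[c.product], c.kcat, c.law, c.Km)
        for c in model.catalytic
    ]

    promoter: PromoterConfig | None = model.promoter
    tf_idx: dict[str, int] = {}
    gene_rows: list[tuple[str, int, float, float]] = []
    erk_active_idx: np.ndarray | None = None
    if promoter is not None:
        tf_idx = {sid: idx[sid] for sid in promoter.tf_species() if sid in idx}
        missing = [sid for sid in promoter.tf_species() if sid not in idx]
        if missing:
            raise KeyError(f"promoter references species absent from the model: {missing}")
        for gene, params in promoter.genes.items():
            gene_rows.append((gene, idx[params.mrna_species], params.ksynth, params.kdeg))
        readouts = model.annotations.get("readouts", {})
        erk_active = readouts.get("ERK", {}).get("active", [])
        if erk_active:
            erk_active_idx = np.array([idx[s] for s in erk_active])

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n)
        yc = np.maximum(y, 0.0)  # rate evaluation robust to solver underflow
        for ridx, pidx, kon, koff in rev:
            v = kon * yc[ridx].prod() - koff * yc[pidx].prod()
            np.add.at(dy, ridx, -v)
            np.add.at(dy, pidx, v)
        for ei, si, pi, kcat, law, km in cat:
            if law == "mass_action":
                v = kcat * yc[ei] * yc[si]
            else:
                v = kcat * yc[ei] * yc[si] / (km + yc[si])
            dy[si] -= v
            dy[pi] += v
        if promoter is not None and not ctx.freeze_mrna:
            state_view = {sid: yc[i] for sid, i in tf_idx.items()}
            f_reg = promoter_regulation_factor(promoter, state_view)
            p = p_rnap_bound(f_reg, promoter)
            for gene, mi, ksynth, kdeg in gene_rows:
                kdeg_eff = kdeg
                if gene == "CCND1" and ctx.destabilization_active():
                    control = ctx.erkpp_control
                    if control is None:
                        raise ValueError(
                            "MEK-inhibited context requires erkpp_control reference"
                        )
                    if erk_active_idx is None:
                        raise ValueError("model lacks an ERK readout annotation")
                    treated = float(yc[erk_active_idx].sum())
                    floor = ctx.erkpp_floor_fraction * control
                    if treated < floor:
                        treated = floor
                        ctx._erkpp_floor_hit = True
                    if treated > 0:
                        kdeg_eff = kdeg * (control / treated)
                ks = 0.0 if ctx.actd else ksynth
                dy[mi] += ks * p - kdeg_eff * yc[mi]
        return dy

    return rhs


def _scaled_norm(f: np.ndarray, y: np.ndarray, settings: SolverSettings) -> float:
    return float(np.max(np.abs(f) / (settings.abs_tol + np.abs(y))))


def equilibrate(
    model: NetworkModel,
    state: np.ndarray | None = None,
    settings: SolverSettings | None = None,
    context: SimulationContext | None = None,
) -> EquilibrationResult:
    """Integrate to quasi-stationary equilibrium.

    Runs the full system (mRNA dynamics included unless the context freezes
    them) in doubling time chunks until the scaled derivative norm falls
    below ``settings.equilibration_tol``, or ``t_max_equilibration`` is
    reached (returned with ``converged=False`` and a warning).  A norm that
    grows while the state diverges raises EquilibrationError.
    """
    settings = settings or SolverSettings()
    ctx = context or SimulationContext()
    y = np.asarray(
        initialize_state(model) if state is None else state, dtype=float
    ).copy()
    rhs = build_rhs(model, ctx)

    norm0 = _scaled_norm(rhs(0.0, y), y, settings)
    if norm0 < settings.equilibration_tol:
        return EquilibrationResult(np.maximum(y, 0.0), 0.0, True, norm0)

    t = 0.0
    chunk = 100.0
    norm = norm0
    while t < settings.t_max_equilibration:
        t_next = min(t + chunk, settings.t_max_equilibration)
        sol = solve_ivp(
            rhs, (t, t_next), y, method="BDF",
            rtol=settings.rel_tol, atol=settings.abs_tol,
            max_step=settings.max_step,
        )
        if not sol.success:
            raise EquilibrationError(f"integrator failed at t={sol.t[-1]:.3g}s: {sol.message}")
        y = sol.y[:, -1]
        t = t_next
        norm = _scaled_norm(rhs(t, y), y, settings)
        if norm < settings.equilibration_tol:
            return EquilibrationResult(np.maximum(y, 0.0), t, True, norm)
        if not np.all(np.isfinite(y)) or (
            np.max(np.abs(y)) > 1e12 and norm > norm0
        ):
            raise EquilibrationError(
                f"system diverging during equilibration (t={t:.3g}s, norm={norm:.3g})"
            )
        chunk *= 2.0
    warnings.warn(
        f"equilibration hit t_max={settings.t_max_equilibration:.3g}s with scaled "
        f"derivative norm {norm:.3g} (tol {settings.equilibration_tol:.3g})",
        RuntimeWarning,
        stacklevel=2,
    )
    return EquilibrationResult(np.maximum(y, 0.0), t, False, norm)


def simulate(
    model: NetworkModel,
    state0: np.ndarray | Mapping[str, float],
    t_end: float,
    settings: SolverSettings | None = None,
    context: SimulationContext | None = None,
    t_eval: Sequence[float] | None = None,
) -> SimulationResult:
    """Simulate a time course from ``state0`` to ``t_end`` (seconds)."""
    settings = settings or SolverSettings()
    ctx = context or SimulationContext()
    idx = model.species_index()
    if isinstance(state0, Mapping):
        y0 = np.zeros(len(model.species))
        for sid, v in state0.items():
            y0[idx[sid]] = v
    else:
        y0 = np.asarray(state0, dtype=float).copy()
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    else:
        t_eval = np.asarray(sorted(set([0.0, *map(float, t_eval), float(t_end)])))
    rhs = build_rhs(model, ctx)
    sol = solve_ivp(
        rhs, (0.0, float(t_end)), y0, method="BDF",
        rtol=settings.rel_tol, atol=settings.abs_tol,
        max_step=settings.max_step, t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failed at t={sol.t[-1]:.3g}s: {sol.message}")
    if ctx._erkpp_floor_hit:
        warnings.warn(
            "ERKPP fell below the destabilization floor during integration; "
            "CCND1 degradation modifier was capped (near-total ERK inhibition)",
            RuntimeWarning,
            stacklevel=2,
        )
    conc = np.maximum(sol.y.T, 0.0)  # clip solver underflow at output only
    return SimulationResult(
        times=sol.t.copy(),
        concentrations=conc,
        species_ids=[s.id for s in model.species],
        metadata=dict(ctx.metadata),
    )
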