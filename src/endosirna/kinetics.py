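"""Hybridization kinetics of sense-antisense dsRNA formation and siRNA yield.

The model formalizes a two-compartment picture of why multi-copy loci feed
RNA interference more efficiently than single-copy loci of equal output:

* Each locus family occupies one or more *local* compartments (the nuclear
  neighborhood of its transcription sites, volume ``V_local``). Tandem and
  clustered families share one compartment; dispersed copies sit in separate
  compartments (one copy each).
* Sense and antisense ssRNA is produced at ``alpha_s``/``alpha_a`` per copy,
  exported to the *bulk* cytoplasm (volume ``V_bulk``) at rate ``e_export``,
  and decays first-order in both compartments.
* Sense and antisense strands anneal into dsRNA by mass action,
  rate = k * n_s * n_a / V per compartment, so the annealing flux scales
  with the product of the two concentrations.
* A single copy can transcribe only one strand at a time. Local annealing is
  therefore gated by the probability phi(m) that, among the m copies in a
  compartment, at least one is sense-engaged and at least one is
  antisense-engaged simultaneously. phi(1) = 0 identically: at a one-copy
  compartment all annealing must happen in the bulk, which is vastly larger.
* dsRNA is processed at rate ``gamma_dicer`` into ``y_sirna`` siRNA duplexes
  per molecule; siRNA decays at ``delta_r``.

Deterministic steady states are available in closed form (the nonlinear
system reduces to one quadratic per compartment class); an exact Gillespie
simulation of the same network, with explicit per-copy engagement states,
serves as the stochastic counterpart.

Time units are arbitrary but must be consistent across all rates; the
defaults are written per minute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

DEFAULT_SIRNA_LENGTH = 23


class KineticsError(ValueError):
    pass


def annealing_rate(n_s: float, n_a: float, V: float, k: float) -> float:
    """Mass-action annealing flux of sense and antisense strands.

    Returns ``k * n_s * n_a / V`` (molecules per unit time per compartment).
    Written on concentrations both strands contribute a 1/V factor, which is
    the inverse-square volume dependence of duplex formation; on molecule
    counts per compartment a single 1/V remains.
    """
    if V <= 0:
        raise KineticsError(f"compartment volume must be > 0, got {V}")
    if n_s < 0 or n_a < 0 or k < 0:
        raise KineticsError("molecule counts and rate constant must be >= 0")
    return k * n_s * n_a / V


def copresence_factor(m: float, q_s: float, q_a: float) -> float:
    """Probability that a compartment with m copies is transcribing both strands.

    Each copy is independently sense-engaged with probability ``q_s``,
    antisense-engaged with ``q_a``, or idle — a single copy can never be both
    (transcriptional mutual exclusion). By inclusion-exclusion the chance
    that at least one copy is sense-engaged AND at least one is
    antisense-engaged is::

        phi(m) = 1 - (1-q_s)^m - (1-q_a)^m + (1-q_s-q_a)^m

    phi(1) = 0 identically, and phi is non-decreasing in m.
    """
    if m < 1:
        raise KineticsError(f"copy count m must be >= 1, got {m}")
    if q_s < 0 or q_a < 0 or q_s + q_a > 1 + 1e-12:
        raise KineticsError(f"need q_s, q_a >= 0 and q_s + q_a <= 1, got {q_s}, {q_a}")
    if m == 1 or q_s == 0 or q_a == 0:
        return 0.0  # a lone copy transcribes one strand at a time
    phi = 1.0 - (1.0 - q_s) ** m - (1.0 - q_a) ** m + max(0.0, 1.0 - q_s - q_a) ** m
    return max(0.0, phi)


@dataclass(frozen=True)
class KineticParams:
    """All rate constants and the copy arrangement of one locus family.

    Defaults describe a moderately expressed, unstable sense-antisense pair
    in a yeast-sized cell, with time in minutes and volumes in units of the
    cell volume: 5-min RNA half-life scale (delta ~ 0.2/min), fast nuclear
    export (1/min), a local transcription-site compartment of ~0.1% of the
    cell volume, and engagement probabilities alpha * tau_occupancy with a
    ~2 min polymerase occupancy per transcript.
    """

    alpha_s: float = 0.1  # sense initiations per copy per minute
    alpha_a: float = 0.1  # antisense initiations per copy per minute
    m: int = 1  # total copy count of the family
    n_compartments: int = 1  # 1 for single/tandem/clustered, m for dispersed
    k_anneal: float = 1e-3  # bimolecular annealing constant (volume/min)
    # a transcription-site neighborhood (~0.1 um radius) is ~1e-4 of a
    # ~40 um^3 yeast cell; this ratio sets the local concentration advantage
    V_local: float = 1e-4  # local compartment volume (cell volumes)
    V_bulk: float = 1.0  # bulk cytoplasmic volume (cell volumes)
    e_export: float = 1.0  # local -> bulk transfer (per min)
    delta_s: float = 0.2  # sense ssRNA decay (per min)
    delta_a: float = 0.2  # antisense ssRNA decay (per min)
    gamma_dicer: float = 0.1  # dsRNA processing (per min)
    y_sirna: int = 0  # siRNA duplexes per dsRNA; 0 -> derived from duplex length
    duplex_length: int = 2000  # bp of dsRNA, used when y_sirna == 0
    sirna_length: int = DEFAULT_SIRNA_LENGTH
    delta_r: float = 0.05  # siRNA decay (per min)
    q_s: float | None = None  # engagement probabilities; None -> alpha * tau
    q_a: float | None = None
    tau_occupancy: float = 2.0  # minutes a copy stays engaged per transcript
    phi_override: float | None = None  # force the co-presence factor (null model)

    def __post_init__(self):
        for name in (
            "alpha_s", "alpha_a", "k_anneal", "V_local", "V_bulk", "e_export",
            "delta_s", "delta_a", "gamma_dicer", "delta_r", "tau_occupancy",
        ):
            if getattr(self, name) < 0:
                raise KineticsError(f"{name} must be >= 0")
        if self.m < 1:
            raise KineticsError("m must be >= 1")
        if not 1 <= self.n_compartments <= self.m:
            raise KineticsError("need 1 <= n_compartments <= m")
        if self.m % self.n_compartments != 0:
            raise KineticsError("m must be divisible by n_compartments")
        if self.V_local > self.V_bulk:
            raise KineticsError("V_local must be <= V_bulk")
        if self.V_local <= 0 or self.V_bulk <= 0:
            raise KineticsError("volumes must be > 0")
        qs, qa = self.engagement_probs()
        if qs + qa > 1 + 1e-12:
            raise KineticsError(f"q_s + q_a must be <= 1, got {qs + qa}")

    # ------------------------------------------------------------------
    def engagement_probs(self) -> tuple[float, float]:
        """(q_s, q_a): per-copy probability of being engaged on each strand."""
        qs = self.q_s if self.q_s is not None else min(self.alpha_s * self.tau_occupancy, 0.49)
        qa = self.q_a if self.q_a is not None else min(self.alpha_a * self.tau_occupancy, 0.49)
        return qs, qa

    @property
    def copies_per_compartment(self) -> int:
        return self.m // self.n_compartments

    @property
    def sirna_yield(self) -> int:
        """siRNA duplexes per diced dsRNA molecule."""
        if self.y_sirna > 0:
            return self.y_sirna
        return max(1, self.duplex_length // self.sirna_length)

    def phi(self) -> float:
        """Co-presence factor of one compartment (possibly overridden)."""
        if self.phi_override is not None:
            return self.phi_override
        qs, qa = self.engagement_probs()
        return copresence_factor(self.copies_per_compartment, qs, qa)

    def for_arrangement(self, arrangement: str, copy_number: int) -> "KineticParams":
        """Derive the compartment layout from a genome arrangement."""
        n = copy_number if arrangement == "dispersed" else 1
        return replace(self, m=copy_number, n_compartments=n)


@dataclass
class SpeciesState:
    """Molecule counts (or deterministic means), totalled over compartments."""

    S_L: float = 0.0  # local sense ssRNA
    A_L: float = 0.0  # local antisense ssRNA
    S_C: float = 0.0  # bulk sense ssRNA
    A_C: float = 0.0  # bulk antisense ssRNA
    D: float = 0.0  # dsRNA
    R: float = 0.0  # siRNA

    @property
    def ssRNA_total(self) -> float:
        return self.S_L + self.A_L + self.S_C + self.A_C

    def as_array(self) -> np.ndarray:
        return np.array([self.S_L, self.A_L, self.S_C, self.A_C, self.D, self.R])


def _bilinear_flux(a_s: float, a_a: float, b_s: float, b_a: float, c: float) -> float:
    """Unique annealing flux u >= 0 solving the coupled pair

        a_s = b_s * S + u,   a_a = b_a * A + u,   u = c * S * A.

    Returns u in [0, min(a_s, a_a)). Uses the numerically stable root of the
    quadratic  c*u^2 - (c*(a_s + a_a) + B)*u + c*a_s*a_a = 0, B = b_s*b_a.
    """
    if c <= 0 or a_s <= 0 or a_a <= 0:
        return 0.0
    B = b_s * b_a
    P = c * (a_s + a_a) + B
    disc = P * P - 4.0 * c * c * a_s * a_a
    u = 2.0 * c * a_s * a_a / (P + math.sqrt(max(disc, 0.0)))
    return min(u, min(a_s, a_a))


def steady_state(params: KineticParams) -> SpeciesState:
    """Deterministic steady state of the two-compartment annealing network.

    Solved exactly: within each compartment class the balance equations
    reduce to a scalar quadratic for the annealing flux, first locally, then
    in the bulk (which receives the summed export of all compartments).
    dsRNA and siRNA follow by back-substitution:
    D = total annealing flux / gamma_dicer, R = gamma_dicer * D * y / delta_r.
    """
    if params.delta_s <= 0 or params.delta_a <= 0 or params.delta_r <= 0:
        raise KineticsError("decay rates must be > 0 for a steady state")
    if params.gamma_dicer <= 0:
        raise KineticsError("gamma_dicer must be > 0 for a steady state")

    m_c = params.copies_per_compartment
    n = params.n_compartments
    phi = params.phi()

    # local compartment (per compartment)
    a_s = m_c * params.alpha_s
    a_a = m_c * params.alpha_a
    b_s = params.e_export + params.delta_s
    b_a = params.e_export + params.delta_a
    c_local = phi * params.k_anneal / params.V_local
    u_local = _bilinear_flux(a_s, a_a, b_s, b_a, c_local)
    S_L = (a_s - u_local) / b_s if b_s > 0 else 0.0
    A_L = (a_a - u_local) / b_a if b_a > 0 else 0.0

    # bulk: fed by export from all n compartments
    s_src = n * params.e_export * S_L
    a_src = n * params.e_export * A_L
    c_bulk = params.k_anneal / params.V_bulk
    u_bulk = _bilinear_flux(s_src, a_src, params.delta_s, params.delta_a, c_bulk)
    S_C = (s_src - u_bulk) / params.delta_s
    A_C = (a_src - u_bulk) / params.delta_a

    flux = n * u_local + u_bulk
    D = flux / params.gamma_dicer
    R = flux * params.sirna_yield / params.delta_r
    return SpeciesState(S_L=n * S_L, A_L=n * A_L, S_C=S_C, A_C=A_C, D=D, R=R)


def pervasive_params(
    copy_number: int = 1,
    arrangement: str = "single",
    steady_molecules: float = 1.0 / 14.0,
    base: KineticParams | None = None,
) -> KineticParams:
    """Parameters for a pervasively transcribed (repressed) locus.

    The per-copy transcription rate is set so that the linear
    (no-annealing) steady state of a *single-copy* locus holds
    ``steady_molecules`` ssRNA molecules per strand — the
    ~one-molecule-per-14-cells regime of a tightly repressed gene. A
    multi-copy family transcribes each copy at that same pervasive level,
    so its total output scales with copy number.
    """
    base = base or KineticParams()
    # linear steady state per strand: alpha*(1/(e+delta) + e/((e+delta)*delta))
    b = base.e_export + base.delta_s
    per_alpha = 1.0 / b + base.e_export / (b * base.delta_s)
    alpha = steady_molecules / per_alpha
    p = replace(base, alpha_s=alpha, alpha_a=alpha)
    return p.for_arrangement(arrangement, copy_number)


# ---------------------------------------------------------------------------
# Gillespie stochastic simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Event-time trajectory of species counts (totalled over compartments)."""

    times: np.ndarray  # event times, starting at 0
    states: np.ndarray  # shape (len(times), 6): S_L, A_L, S_C, A_C, D, R
    t_end: float

    def time_average(self, burn_in: float = 0.0) -> SpeciesState:
        """Time-weighted average state over (burn_in, t_end]."""
        t = np.append(self.times, self.t_end)
        dt = np.diff(np.clip(t, burn_in, None))
        total = dt.sum()
        if total <= 0:
            raise KineticsError("burn_in >= t_end: nothing to average")
        mean = (self.states * dt[:, None]).sum(axis=0) / total
        return SpeciesState(*mean)

    def final_state(self) -> SpeciesState:
        return SpeciesState(*self.states[-1])


def gillespie(
    params: KineticParams,
    t_max: float,
    seed: int,
    record: bool = True,
    max_events: int = 20_000_000,
) -> Trajectory:
    """Exact stochastic simulation of the annealing network.

    Species are integer counts; each of the ``n_compartments`` compartments
    carries its own local pools and per-copy engagement states. Copies
    switch idle -> sense/antisense engaged and back with rates whose
    stationary law matches (q_s, q_a); local annealing in a compartment is
    only possible while at least one copy is sense-engaged and at least one
    is antisense-engaged (so a 1-copy compartment never anneals locally).

    With ``phi_override`` set, the engagement gate is replaced by a constant
    factor — the mechanism-off null used for calibration runs.
    """
    if t_max <= 0:
        raise KineticsError("t_max must be > 0")
    rng = np.random.default_rng(seed)
    qs, qa = params.engagement_probs()
    m_c = params.copies_per_compartment
    n = params.n_compartments
    y = params.sirna_yield
    use_gate = params.phi_override is None

    # engagement switching: 3-state chain per copy, off-rate mu = 1/tau,
    # on-rates chosen so the stationary distribution is (q_s, q_a, idle)
    mu = 1.0 / params.tau_occupancy if params.tau_occupancy > 0 else 0.0
    idle = max(1e-12, 1.0 - qs - qa)
    lam_s = mu * qs / idle
    lam_a = mu * qa / idle

    # state: per-compartment local pools and engagement counts (Python ints;
    # propensity updates stay scalar, which keeps the event loop fast)
    SL = [0] * n
    AL = [0] * n
    ES = [0] * n
    EA = [0] * n
    S_C = A_C = D = R = 0
    t = 0.0
    times = [0.0]
    states = [(0, 0, 0, 0, 0, 0)]

    alpha_s_c = params.alpha_s * m_c
    alpha_a_c = params.alpha_a * m_c
    e = params.e_export
    ds, da = params.delta_s, params.delta_a
    k_loc = params.k_anneal / params.V_local
    k_blk = params.k_anneal / params.V_bulk
    phi_const = params.phi_override if params.phi_override is not None else 1.0
    rand = rng.random
    props = [0.0] * (11 * n + 5)

    for _ in range(max_events):
        for c in range(n):
            gate = (ES[c] > 0 and EA[c] > 0) if use_gate else True
            base = 11 * c
            props[base] = phi_const * k_loc * SL[c] * AL[c] if gate else 0.0
            props[base + 1] = alpha_s_c
            props[base + 2] = alpha_a_c
            props[base + 3] = e * SL[c]
            props[base + 4] = e * AL[c]
            props[base + 5] = ds * SL[c]
            props[base + 6] = da * AL[c]
            free = m_c - ES[c] - EA[c]
            props[base + 7] = lam_s * free
            props[base + 8] = mu * ES[c]
            props[base + 9] = lam_a * free
            props[base + 10] = mu * EA[c]
        g0 = 11 * n
        props[g0] = k_blk * S_C * A_C
        props[g0 + 1] = ds * S_C
        props[g0 + 2] = da * A_C
        props[g0 + 3] = params.gamma_dicer * D
        props[g0 + 4] = params.delta_r * R
        total = sum(props)
        if total <= 0:
            break
        t -= math.log(1.0 - rand()) / total
        if t > t_max:
            break
        # pick reaction by linear scan of the cumulative propensity
        u = rand() * total
        acc = 0.0
        j = 0
        for j, a in enumerate(props):
            acc += a
            if u < acc:
                break
        if j < g0:
            c, rxn = divmod(j, 11)
            if rxn == 0:
                SL[c] -= 1
                AL[c] -= 1
                D += 1
            elif rxn == 1:
                SL[c] += 1
            elif rxn == 2:
                AL[c] += 1
            elif rxn == 3:
                SL[c] -= 1
                S_C += 1
            elif rxn == 4:
                AL[c] -= 1
                A_C += 1
            elif rxn == 5:
                SL[c] -= 1
            elif rxn == 6:
                AL[c] -= 1
            elif rxn == 7:
                ES[c] += 1
            elif rxn == 8:
                ES[c] -= 1
            elif rxn == 9:
                EA[c] += 1
            else:
                EA[c] -= 1
        else:
            g = j - g0
            if g == 0:
                S_C -= 1
                A_C -= 1
                D += 1
            elif g == 1:
                S_C -= 1
            elif g == 2:
                A_C -= 1
            elif g == 3:
                D -= 1
                R += y
            else:
                R -= 1
        if record:
            times.append(t)
            states.append((sum(SL), sum(AL), S_C, A_C, D, R))
    else:
        raise KineticsError("max_events exceeded before t_max")

    if not record:
        times = [0.0, min(t, t_max)]
        states = [states[0], (sum(SL), sum(AL), S_C, A_C, D, R)]
    return Trajectory(
        times=np.asarray(times), states=np.asarray(states, dtype=float), t_end=t_max
    )
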