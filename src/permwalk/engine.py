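"""Monte Carlo random-walk engine for permeable layered 1D domains.

Each of ``Np`` independent walkers takes fixed-length steps
``δx = ± sqrt(2 D_i δt)`` with equal sign probability.  A step that would
cross a membrane at ``x_b`` is split into ``δx_i`` (walker to barrier) and
``δx_j`` (remainder); a uniform draw against the transit probability decides
the outcome:

* transmit — the walker continues past the membrane, the remaining sub-step
  rescaled by ``sqrt(D_j / D_i)`` so the fractional time budget is preserved:
  ``x = x_b ± |δx_j| sqrt(D_j/D_i)``;
* reflect — elastically back into the incident compartment:
  ``x = x_b ∓ |δx_j|``.

Two transit models are provided.  The *reference* model uses only the
membrane permeability, ``p = 2κδx_i / (D_i + 2κδx_i)``.  The *hybrid* model
factorizes membrane transit and the diffusivity step as two independent
events separated by an infinitesimal gap,
``p = p_ref · min(1, sqrt(D_j/D_i))``; when the diffusivity is continuous the
two models coincide exactly, and in the κ → ∞ limit the hybrid model reduces
to the classical acceptance rule for a bare diffusivity step.

The step budget must satisfy ``δt ≤ min_i L_i²/(2 D_i)`` so that a walker can
interact with at most one membrane per step; violating configurations are
rejected rather than clamped.

Draw order per step (reproducibility contract): one sign array for all
walkers, then one uniform array for all walkers (the uniform is consumed by
the transit decision and ignored by walkers that do not meet a membrane).
The numba and pure-numpy kernels are bit-identical given the same draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain import Domain1D, DomainError, max_timestep_domain

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "MODEL_REFERENCE",
    "MODEL_HYBRID",
    "SimConfig",
    "WalkerEnsemble",
    "CrossingLedger",
    "SimulationResult",
    "transit_probability_reference",
    "transit_probability_hybrid",
    "seed_walkers",
    "step_ensemble",
    "run_simulation",
    "density_histogram",
]

MODEL_REFERENCE = "reference"
MODEL_HYBRID = "hybrid"
_MODEL_CODES = {MODEL_REFERENCE: 0, MODEL_HYBRID: 1}


def transit_probability_reference(D_i: float, kappa: float,
                                  dx_i: float) -> float:
    """Membrane transit probability ``2κδx_i / (D_i + 2κδx_i)``.

    ``dx_i`` is the distance from the walker to the membrane at the moment
    of the attempt.  Lies in [0, 1); 0 for an impermeable membrane.
    """
    if D_i <= 0:
        raise DomainError("diffusivity must be positive")
    if kappa < 0:
        raise DomainError("permeability must be nonnegative")
    if dx_i < 0:
        raise DomainError("distance to barrier must be nonnegative")
    return 2.0 * kappa * dx_i / (D_i + 2.0 * kappa * dx_i)


def transit_probability_hybrid(D_i: float, D_j: float, kappa: float,
                               dx_i: float) -> float:
    """Hybrid transit probability ``p_b · p_d`` with
    ``p_d = min(1, sqrt(D_j / D_i))``.

    The membrane and the diffusivity step are treated as two interactions in
    sequence, with the membrane placed on the low-diffusivity side.  Stepping
    toward equal or higher diffusivity, ``p_d = 1`` and ``p_b`` is the
    reference probability with the incident values.  Stepping toward lower
    diffusivity, the walker first passes the diffusivity step (``p_d``) and
    then meets the membrane inside the slow medium, so ``p_b`` is evaluated
    with ``D_j`` and the incident distance rescaled onto the slow side
    (``δx_i sqrt(D_j/D_i)``), which simplifies to
    ``2κδx_i / (sqrt(D_i D_j) + 2κδx_i)``.  This is the unique combination
    that preserves a uniform density at equilibrium for every κ, and it
    reduces to the bare diffusivity-step acceptance ``sqrt(D_j/D_i)`` as
    κ → ∞.  With continuous diffusivity the hybrid and reference models are
    identical.
    """
    if D_j <= 0:
        raise DomainError("diffusivity must be positive")
    if D_j >= D_i:
        return transit_probability_reference(D_i, kappa, dx_i)
    if kappa < 0:
        raise DomainError("permeability must be nonnegative")
    if dx_i < 0:
        raise DomainError("distance to barrier must be nonnegative")
    return (np.sqrt(D_j / D_i) * 2.0 * kappa * dx_i
            / (np.sqrt(D_i * D_j) + 2.0 * kappa * dx_i))


@dataclass
class SimConfig:
    """Monte Carlo run settings.

    seeding: ``("delta", x0)``, ``("uniform", None)`` for the whole domain,
    or ``("uniform", (a, b))`` for an interval.
    """

    dt: float                      # ms
    T: float                       # ms
    Np: int
    seed: int = 0
    seeding: tuple = ("uniform", None)
    model: str = MODEL_HYBRID
    histogram_bin_width: float = 1.0  # µm
    record_flux: bool = False
    snapshot_times: tuple = ()
    kernel: str = "numba"          # "numba" | "numpy"

    def validate(self, domain: Domain1D) -> None:
        if self.dt <= 0:
            raise DomainError("dt must be positive")
        dt_max = max_timestep_domain(domain)
        if self.dt > dt_max * (1 + 1e-12):
            raise DomainError(
                f"dt={self.dt} exceeds single-crossing limit dt_max={dt_max}")
        if self.T < self.dt:
            raise DomainError("T must be at least one step")
        if self.Np < 1:
            raise DomainError("need at least one walker")
        if self.model not in _MODEL_CODES:
            raise DomainError(f"unknown transit model {self.model!r}")


@dataclass
class WalkerEnsemble:
    """Positions and per-walker compartment state of Np walkers."""

    positions: np.ndarray
    initial_positions: np.ndarray
    compartment: np.ndarray        # 0-based current compartment per walker
    time: float
    rng: np.random.Generator

    @property
    def Np(self) -> int:
        return self.positions.size


@dataclass
class CrossingLedger:
    """Per-step, per-barrier transmission counts (left→right / right→left).

    Arrays have shape ``(n_steps, m+1)`` indexed by barrier; only internal
    barriers 1..m-1 ever record crossings.
    """

    count_lr: np.ndarray
    count_rl: np.ndarray
    Np: int
    dt: float


@dataclass
class SimulationResult:
    ensemble: WalkerEnsemble
    snapshots: dict            # time -> positions copy
    ledger: CrossingLedger | None
    config: SimConfig
    domain: Domain1D


def seed_walkers(seeding, Np: int, domain: Domain1D,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw initial walker positions for a seeding spec."""
    kind, arg = seeding
    b0, bm = domain.barriers[0], domain.barriers[-1]
    if kind == "delta":
        x0 = float(arg)
        if not b0 <= x0 <= bm:
            raise DomainError("delta seeding point outside domain")
        return np.full(Np, x0)
    if kind == "uniform":
        a, b = (b0, bm) if arg is None else arg
        if a > b or a < b0 or b > bm:
            raise DomainError("seeding interval outside domain")
        return rng.uniform(a, b, Np)
    raise DomainError(f"unknown seeding mode {kind!r}")


@njit(cache=True)
def _kernel_numba(x, comp, signs, uniforms, barriers, D, kappa, sqrt2Ddt,
                  model_code, count_lr, count_rl):
    m = D.size
    for p in range(x.size):
        i = comp[p]
        s = 1.0 if signs[p] else -1.0
        step = sqrt2Ddt[i]
        xn = x[p] + s * step
        if s > 0.0:
            bb = barriers[i + 1]
            if xn < bb:
                x[p] = xn
                continue
            j = i + 1
            iface = i + 1
        else:
            bb = barriers[i]
            if xn > bb:
                x[p] = xn
                continue
            j = i - 1
            iface = i
        dxj = step - abs(bb - x[p])
        k = kappa[iface]
        if k == 0.0:
            x[p] = bb - s * dxj
            continue
        Di = D[i]
        Dj = D[j]
        dxi = step - dxj
        if model_code == 1 and Dj < Di:
            # hybrid, entering the slower side: membrane sits in the slow
            # medium, so p_b sees D_j and the distance rescaled onto it
            pt = (np.sqrt(Dj / Di) * 2.0 * k * dxi
                  / (np.sqrt(Di * Dj) + 2.0 * k * dxi))
        else:
            pt = 2.0 * k * dxi / (Di + 2.0 * k * dxi)
        if uniforms[p] < pt:
            x[p] = bb + s * dxj * np.sqrt(Dj / Di)
            comp[p] = j
            if s > 0.0:
                count_lr[iface] += 1
            else:
                count_rl[iface] += 1
        else:
            x[p] = bb - s * dxj


def _kernel_numpy(x, comp, signs, uniforms, barriers, D, kappa, sqrt2Ddt,
                  model_code, count_lr, count_rl):
    """Vectorized twin of the numba kernel (same arithmetic per walker)."""
    s = np.where(signs, 1.0, -1.0)
    step = sqrt2Ddt[comp]
    xn = x + s * step
    bb = np.where(signs, barriers[comp + 1], barriers[comp])
    crossing = np.where(signs, xn >= bb, xn <= bb)
    x[~crossing] = xn[~crossing]
    if not np.any(crossing):
        return
    idx = np.nonzero(crossing)[0]
    sc = s[idx]
    bc = bb[idx]
    ic = comp[idx]
    jc = ic + np.where(signs[idx], 1, -1)
    iface = np.where(signs[idx], ic + 1, ic)
    dxj = step[idx] - np.abs(bc - x[idx])
    k = kappa[iface]
    dxi = step[idx] - dxj
    with np.errstate(divide="ignore", invalid="ignore"):
        pt = 2.0 * k * dxi / (D[ic] + 2.0 * k * dxi)
        jc_safe = np.clip(jc, 0, D.size - 1)
        if model_code == 1:
            Di, Dj = D[ic], D[jc_safe]
            pt_slow = (np.sqrt(Dj / Di) * 2.0 * k * dxi
                       / (np.sqrt(Di * Dj) + 2.0 * k * dxi))
            pt = np.where(Dj < Di, pt_slow, pt)
    transmit = (k > 0) & (uniforms[idx] < pt)
    rescale = np.sqrt(D[jc_safe] / D[ic])
    x[idx] = np.where(transmit, bc + sc * dxj * rescale, bc - sc * dxj)
    comp[idx[transmit]] = jc[transmit]
    tr_iface = iface[transmit]
    tr_pos = signs[idx][transmit]
    np.add.at(count_lr, tr_iface[tr_pos], 1)
    np.add.at(count_rl, tr_iface[~tr_pos], 1)


def step_ensemble(ensemble: WalkerEnsemble, domain: Domain1D,
                  config: SimConfig, signs=None, uniforms=None):
    """Advance the ensemble by one step; returns (count_lr, count_rl) per
    barrier for this step.

    ``signs``/``uniforms`` may be injected for deterministic tests; by
    default they are drawn from the ensemble RNG (signs first, then the
    transit uniforms).
    """
    Np = ensemble.Np
    if signs is None:
        signs = ensemble.rng.integers(0, 2, Np).astype(np.bool_)
    if uniforms is None:
        uniforms = ensemble.rng.random(Np)
    count_lr = np.zeros(domain.m + 1, dtype=np.int64)
    count_rl = np.zeros(domain.m + 1, dtype=np.int64)
    sqrt2Ddt = np.sqrt(2.0 * domain.diffusivities * config.dt)
    kernel = _kernel_numba if (config.kernel == "numba" and HAVE_NUMBA) \
        else _kernel_numpy
    kernel(ensemble.positions, ensemble.compartment, signs, uniforms,
           domain.barriers, domain.diffusivities, domain.permeabilities,
           sqrt2Ddt, _MODEL_CODES[config.model], count_lr, count_rl)
    ensemble.time += config.dt
    return count_lr, count_rl


def _initial_ensemble(domain: Domain1D, config: SimConfig) -> WalkerEnsemble:
    rng = np.random.default_rng(config.seed)
    x = seed_walkers(config.seeding, config.Np, domain, rng)
    comp = np.asarray(domain.locate(x), dtype=np.int64) - 1
    return WalkerEnsemble(x.copy(), x.copy(), comp, 0.0, rng)


def run_simulation(domain: Domain1D, config: SimConfig) -> SimulationResult:
    """Run ``ceil(T/δt)`` steps from the seeded initial condition.

    Deterministic given (domain, config, seed).  Snapshots copy the position
    array at the first step time reaching each requested time; the crossing
    ledger covers every step when ``record_flux`` is set.
    """
    config.validate(domain)
    ens = _initial_ensemble(domain, config)
    n_steps = int(np.ceil(config.T / config.dt - 1e-9))
    ledger = None
    if config.record_flux:
        ledger = CrossingLedger(
            np.zeros((n_steps, domain.m + 1), dtype=np.int64),
            np.zeros((n_steps, domain.m + 1), dtype=np.int64),
            config.Np, config.dt)
    snap_times = sorted(config.snapshot_times)
    snapshots = {}
    si = 0
    sqrt2Ddt = np.sqrt(2.0 * domain.diffusivities * config.dt)
    kernel = _kernel_numba if (config.kernel == "numba" and HAVE_NUMBA) \
        else _kernel_numpy
    model_code = _MODEL_CODES[config.model]
    lr = np.zeros(domain.m + 1, dtype=np.int64)
    rl = np.zeros(domain.m + 1, dtype=np.int64)
    for k in range(n_steps):
        signs = ens.rng.integers(0, 2, config.Np).astype(np.bool_)
        uniforms = ens.rng.random(config.Np)
        if ledger is not None:
            lr = ledger.count_lr[k]
            rl = ledger.count_rl[k]
        else:
            lr[:] = 0
            rl[:] = 0
        kernel(ens.positions, ens.compartment, signs, uniforms,
               domain.barriers, domain.diffusivities, domain.permeabilities,
               sqrt2Ddt, model_code, lr, rl)
        ens.time = (k + 1) * config.dt
        while si < len(snap_times) and ens.time >= snap_times[si] - 1e-9:
            snapshots[snap_times[si]] = ens.positions.copy()
            si += 1
    return SimulationResult(ens, snapshots, ledger, config, domain)


def density_histogram(positions: np.ndarray, bin_width: float,
                      domain: Domain1D):
    """Density-normalized position histogram.

    Bins tile [b_0, b_m]; the last bin absorbs any remainder so widths may
    differ there.  Returns (bin_centers, densities) with
    ``ρ_bin = count / (Np · w_bin)`` so that Σ ρ w = 1.
    """
    if bin_width <= 0:
        raise DomainError("bin width must be positive")
    b0, bm = domain.barriers[0], domain.barriers[-1]
    n_bins = max(1, int(np.ceil((bm - b0) / bin_width - 1e-9)))
    edges = b0 + bin_width * np.arange(n_bins + 1)
    edges[-1] = bm
    counts, _ = np.histogram(positions, bins=edges)
    widths = np.diff(edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho = counts / (positions.size * widths)
    return centers, rho


def compartment_fractions(positions: np.ndarray, domain: Domain1D) -> np.ndarray:
    """Fraction of walkers in each compartment (stateless barrier tie-break)."""
    comp = np.asarray(domain.locate(positions)) - 1
    return np.bincount(comp, minlength=domain.m) / positions.size
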