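"""1D layered domains: geometry, validation, time-step limits, histology synthesis.

A domain is an ordered array of ``m`` compartments spanning ``[b_0, b_m]``,
each with a constant diffusivity ``D_i`` (µm²/ms), separated by semi-permeable
membranes with permeability ``kappa_i`` (µm/ms).  The two end barriers are
always impermeable (``kappa_0 = kappa_m = 0``): walkers never leave the domain.

Units throughout the package: lengths in µm, times in ms, diffusivities in
µm²/ms, permeabilities in µm/ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Domain1D",
    "DomainError",
    "HistologyStats",
    "build_domain",
    "max_timestep_domain",
    "max_timestep_reference",
    "max_timestep_reference_domain",
    "synthesize_histology_domain",
    "area_to_diameter",
]


class DomainError(ValueError):
    """Raised for invalid domain geometry or parameters."""


@dataclass(frozen=True)
class Domain1D:
    """An ordered 1D array of compartments separated by permeable membranes.

    Parameters
    ----------
    barriers : ndarray, shape (m+1,)
        Strictly increasing barrier positions ``b_0 .. b_m`` in µm.
    diffusivities : ndarray, shape (m,)
        Diffusivity ``D_i`` of compartment ``i`` (1-based in formulas,
        0-based in arrays), spanning ``[b_{i-1}, b_i]``.
    permeabilities : ndarray, shape (m+1,)
        Membrane permeability at each barrier; the end entries must be 0.
    labels : tuple of str, optional
        Per-compartment tag (``"ICS"``/``"ECS"``), used by the histology
        generator; purely informational.
    """

    barriers: np.ndarray
    diffusivities: np.ndarray
    permeabilities: np.ndarray
    labels: tuple | None = None

    def __post_init__(self):
        b = np.asarray(self.barriers, dtype=float)
        d = np.asarray(self.diffusivities, dtype=float)
        k = np.asarray(self.permeabilities, dtype=float)
        object.__setattr__(self, "barriers", b)
        object.__setattr__(self, "diffusivities", d)
        object.__setattr__(self, "permeabilities", k)
        if b.ndim != 1 or b.size < 2:
            raise DomainError("need at least one compartment (two barriers)")
        if d.size != b.size - 1:
            raise DomainError(
                f"{d.size} diffusivities for {b.size - 1} compartments"
            )
        if k.size != b.size:
            raise DomainError(f"{k.size} permeabilities for {b.size} barriers")
        db = np.diff(b)
        if not np.all(db > 0):
            i = int(np.argmin(db > 0))
            raise DomainError(f"barriers not strictly increasing at index {i + 1}")
        if not np.all(d > 0):
            i = int(np.argmin(d > 0))
            raise DomainError(f"non-positive diffusivity at compartment {i}")
        if not np.all(k >= 0):
            i = int(np.argmin(k >= 0))
            raise DomainError(f"negative permeability at barrier {i}")
        if k[0] != 0 or k[-1] != 0:
            raise DomainError("end barriers must be impermeable (kappa = 0)")
        if self.labels is not None and len(self.labels) != d.size:
            raise DomainError("one label per compartment required")

    @property
    def m(self) -> int:
        """Number of compartments."""
        return self.barriers.size - 1

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.barriers)

    @property
    def total_length(self) -> float:
        return float(self.barriers[-1] - self.barriers[0])

    def locate(self, x) -> np.ndarray | int:
        """Stateless compartment lookup: 1-based index of the compartment
        containing ``x``.

        Compartments are half-open ``[b_{i-1}, b_i)``; a point exactly on an
        internal barrier maps to the compartment on its right, and the right
        end ``b_m`` maps to compartment ``m``.  (The walker engine instead
        keeps explicit per-walker compartment state so that barrier-exact
        positions are resolved by history, not by this tie-break.)
        """
        xa = np.asarray(x, dtype=float)
        if np.any(xa < self.barriers[0]) or np.any(xa > self.barriers[-1]):
            raise DomainError(
                f"position outside domain [{self.barriers[0]}, {self.barriers[-1]}]"
            )
        idx = np.searchsorted(self.barriers, xa, side="right")
        idx = np.clip(idx, 1, self.m)
        return idx if xa.ndim else int(idx)


def build_domain(lengths, diffusivities, internal_permeabilities, origin=0.0,
                 labels=None) -> Domain1D:
    """Assemble a :class:`Domain1D` from compartment lengths.

    ``internal_permeabilities`` has one entry per internal barrier
    (``len(lengths) - 1``); end barriers are set impermeable.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.ndim != 1 or lengths.size == 0:
        raise DomainError("need at least one compartment length")
    if not np.all(lengths > 0):
        i = int(np.argmin(lengths > 0))
        raise DomainError(f"non-positive length at compartment {i}")
    diffusivities = np.asarray(diffusivities, dtype=float)
    if diffusivities.size != lengths.size:
        raise DomainError("one diffusivity per compartment required")
    kin = np.asarray(internal_permeabilities, dtype=float)
    if kin.size != lengths.size - 1:
        raise DomainError(
            f"{kin.size} internal permeabilities for {lengths.size} compartments"
        )
    barriers = float(origin) + np.concatenate([[0.0], np.cumsum(lengths)])
    kappa = np.concatenate([[0.0], kin, [0.0]])
    return Domain1D(barriers, diffusivities, kappa,
                    tuple(labels) if labels is not None else None)


def max_timestep_domain(domain: Domain1D) -> float:
    """Largest time step for which a single step cannot span a compartment:
    ``min_i L_i² / (2 D_i)`` (ms)."""
    L = domain.lengths
    return float(np.min(L * L / (2.0 * domain.diffusivities)))


def max_timestep_reference(D, kappa, p_max: float = 0.01):
    """Time-step bound keeping the reference transit probability below ``p_max``.

    Solves ``2 κ δx / (D + 2 κ δx) = p_max`` at the worst-case sub-step
    ``δx = sqrt(2 D δt)``, giving the closed form
    ``δt = p_max² D / (8 κ² (1 − p_max)²)``.  An impermeable barrier
    (κ = 0) imposes no restriction and returns ``inf``.

    For a whole domain use :func:`max_timestep_reference_domain`, which takes
    the minimum over all (compartment, adjacent-interface) pairs.
    """
    if not 0 < p_max < 1:
        raise DomainError("p_max must be in (0, 1)")
    if D <= 0:
        raise DomainError("diffusivity must be positive")
    if kappa < 0:
        raise DomainError("permeability must be nonnegative")
    if kappa == 0:
        return math.inf
    return p_max * p_max * D / (8.0 * kappa * kappa * (1.0 - p_max) ** 2)


def max_timestep_reference_domain(domain: Domain1D, p_max: float = 0.01) -> float:
    """Reference-model step limit for a whole domain: minimum of the scalar
    bound over every compartment/adjacent-internal-barrier pair."""
    best = math.inf
    for i in range(domain.m):
        for b in (i, i + 1):  # left and right barrier of compartment i
            k = domain.permeabilities[b]
            if k > 0:
                best = min(best, max_timestep_reference(
                    float(domain.diffusivities[i]), float(k), p_max))
    return best


def area_to_diameter(area: float) -> float:
    """Diameter of a circle with the given cross-sectional area: ``2 sqrt(A/π)``."""
    if area <= 0:
        raise DomainError("area must be positive")
    return 2.0 * math.sqrt(area / math.pi)


@dataclass(frozen=True)
class HistologyStats:
    """Summary statistics describing a myocardium cross-section.

    Cell cross-sectional areas follow a normal distribution truncated at
    ``mean ± 2 sd``; extracellular gaps are uniform on ``ecs_range``.  The
    defaults describe swine mesocardium: mean cell area 120 µm² (sd 40 µm²,
    i.e. a mean diameter near 12.4 µm for circular cross-sections) and
    3–5 µm extracellular gaps, assembled into a 49.5 µm domain.
    """

    mean_area: float = 120.0   # µm²
    sd_area: float = 40.0      # µm²
    ecs_range: tuple = (3.0, 5.0)  # µm
    total_length: float = 49.5     # µm
    d_ics: float = 0.5         # µm²/ms
    d_ecs: float = 2.0         # µm²/ms
    kappa: float = 0.05        # µm/ms

    def __post_init__(self):
        if self.mean_area <= 0:
            raise DomainError("mean_area must be positive")
        if self.sd_area < 0:
            raise DomainError("sd_area must be nonnegative")
        if self.ecs_range[0] > self.ecs_range[1] or self.ecs_range[0] < 0:
            raise DomainError("invalid ecs_range")
        if self.total_length <= 0:
            raise DomainError("total_length must be positive")


def _draw_truncated_area(stats: HistologyStats, rng: np.random.Generator) -> float:
    # Rejection from the untruncated normal; exact for the ±2σ clipping.
    if stats.sd_area == 0:
        return stats.mean_area
    lo = stats.mean_area - 2.0 * stats.sd_area
    hi = stats.mean_area + 2.0 * stats.sd_area
    while True:
        a = rng.normal(stats.mean_area, stats.sd_area)
        if lo <= a <= hi and a > 0:
            return a


def synthesize_histology_domain(stats: HistologyStats | None = None,
                                seed=0, start_with: str = "ICS") -> Domain1D:
    """Synthesize an alternating ICS/ECS domain from histology statistics.

    ICS compartment lengths are diameters of circles whose areas are drawn
    from the truncated normal; ECS lengths are uniform on ``ecs_range``.
    Drawing alternates (default starting with ICS) until the cumulative
    length would exceed ``total_length``; the final compartment is truncated
    so the total is exact.  All internal membranes share ``stats.kappa``.
    """
    stats = stats or HistologyStats()
    rng = np.random.default_rng(seed)
    if start_with not in ("ICS", "ECS"):
        raise DomainError("start_with must be 'ICS' or 'ECS'")
    lengths, labels = [], []
    kind = start_with
    total = 0.0
    while total < stats.total_length:
        if kind == "ICS":
            length = area_to_diameter(_draw_truncated_area(stats, rng))
        else:
            length = rng.uniform(*stats.ecs_range)
        if total + length >= stats.total_length:
            length = stats.total_length - total
        if length > 0:
            lengths.append(length)
            labels.append(kind)
            total += length
        kind = "ECS" if kind == "ICS" else "ICS"
    D = [stats.d_ics if lab == "ICS" else stats.d_ecs for lab in labels]
    kin = [stats.kappa] * (len(lengths) - 1)
    dom = build_domain(lengths, D, kin, labels=labels)
    # Guarantee the advertised exact total despite float accumulation.
    b = dom.barriers.copy()
    b[-1] = stats.total_length
    return Domain1D(b, dom.diffusivities, dom.permeabilities, dom.labels)
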