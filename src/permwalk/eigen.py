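"""Eigenmode expansion of the 1D layered diffusion operator.

Separation of variables in a domain of ``m`` compartments with sealed ends
reduces the diffusion equation to a Helmholtz problem per compartment,
``D_i u'' + λ u = 0``, coupled at each internal membrane by continuity of the
diffusive flux and the permeability jump condition

    D_i u'|_L  =  D_j u'|_R  =  κ (u|_R − u|_L).

Inside compartment i the solution is ``A cos(α_i ξ) + B sin(α_i ξ)`` with
``α_i = sqrt(λ / D_i)`` and ξ the offset from the compartment's left barrier.
Eigenvalues are located as sign changes of a characteristic function F(λ)
built by propagating the boundary data (u, φ = D u') across the domain;
F is the sealed-end flux residual at the right boundary.  The propagator is

    U(x, t) = Σ_n exp(−λ_n t) ν_n(x) w_n

with orthonormal modes ν_n and initial-condition weights w_n (ν_n(x₀) for a
delta release, a mode average for a uniform one).  With sealed ends the
spectrum starts at the constant mode λ₁ = 0, ν₁ = 1/sqrt(Σ L_i), so U relaxes
to the uniform density 1/(b_m − b_0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .domain import Domain1D, DomainError

__all__ = [
    "EigenSpectrum",
    "DensityField",
    "characteristic_function",
    "find_eigenvalues",
    "eigenmode_eval",
    "propagator_delta",
    "propagator_uniform",
    "steady_density",
]


@dataclass(frozen=True)
class DensityField:
    """Particle density U(x, t) sampled on a grid (1/µm)."""

    x: np.ndarray
    values: np.ndarray
    time: float
    provenance: str = "eigen"

    def mass(self) -> float:
        """Trapezoidal integral of U over the grid."""
        return float(np.trapezoid(self.values, self.x))


@dataclass(frozen=True)
class EigenSpectrum:
    """Eigenvalues and normalized piecewise-trigonometric eigenmodes.

    ``coeffs[n, i]`` holds the pair (A, B) of mode n in compartment i, in the
    local coordinate ξ = x − b_i (left edge of the compartment), already
    scaled so that ∫ ν_n² dx = 1 over the whole domain.  Mode 0 is the
    constant mode λ = 0 (A = 1/sqrt(ΣL), B = 0 everywhere).
    """

    domain: Domain1D
    eigenvalues: np.ndarray          # (N,), ascending, eigenvalues[0] == 0
    coeffs: np.ndarray               # (N, m, 2)
    scan_lambda_max: float
    scan_points: int

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    def alphas(self) -> np.ndarray:
        """Local wavenumbers α_{n,i} = sqrt(λ_n / D_i), shape (N, m)."""
        lam = self.eigenvalues[:, None]
        return np.sqrt(lam / self.domain.diffusivities[None, :])

    # -- evaluation ---------------------------------------------------------

    def eval_matrix(self, x: np.ndarray) -> np.ndarray:
        """Evaluate every mode at every grid point; shape (N, len(x)).

        Points exactly on a barrier use the right compartment's basis
        (stateless tie-break; modes jump at membranes).
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        comp = self.domain.locate(x) - 1  # 0-based
        out = np.empty((self.n_modes, x.size))
        alphas = self.alphas()
        for i in range(self.domain.m):
            sel = comp == i
            if not np.any(sel):
                continue
            xi = x[sel] - self.domain.barriers[i]
            a = alphas[:, i, None] * xi[None, :]
            out[:, sel] = (self.coeffs[:, i, 0, None] * np.cos(a)
                           + self.coeffs[:, i, 1, None] * np.sin(a))
        return out

    def eval_matrix_compartment(self, x: np.ndarray, i: int) -> np.ndarray:
        """Evaluate every mode using compartment ``i``'s basis (0-based).

        Needed for one-sided values at barriers, where modes jump.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        xi = x - self.domain.barriers[i]
        a = self.alphas()[:, i, None] * xi[None, :]
        return (self.coeffs[:, i, 0, None] * np.cos(a)
                + self.coeffs[:, i, 1, None] * np.sin(a))

    def interface_values(self, n: int, interface: int) -> tuple[float, float]:
        """One-sided mode values (ν_n(b⁻), ν_n(b⁺)) at internal barrier
        ``interface`` (1-based, 1..m-1)."""
        if not 1 <= interface <= self.domain.m - 1:
            raise DomainError("not an internal interface")
        i = interface - 1
        L = self.domain.lengths[i]
        al = self.alphas()[n, i]
        A, B = self.coeffs[n, i]
        left = A * np.cos(al * L) + B * np.sin(al * L)
        right = self.coeffs[n, interface, 0]  # ξ = 0 in the right compartment
        return float(left), float(right)

    def interface_matrix(self, interface: int) -> np.ndarray:
        """(ν_n(b⁻), ν_n(b⁺)) for every mode, shape (N, 2)."""
        i = interface - 1
        L = self.domain.lengths[i]
        al = self.alphas()[:, i]
        A, B = self.coeffs[:, i, 0], self.coeffs[:, i, 1]
        left = A * np.cos(al * L) + B * np.sin(al * L)
        right = self.coeffs[:, interface, 0]
        return np.column_stack([left, right])

    def mode_integrals(self, a: float, b: float) -> np.ndarray:
        """∫_a^b ν_n(x) dx for every mode, in closed form per compartment."""
        dom = self.domain
        if a > b:
            raise DomainError("empty integration interval")
        if a < dom.barriers[0] or b > dom.barriers[-1]:
            raise DomainError("integration interval outside domain")
        out = np.zeros(self.n_modes)
        alphas = self.alphas()
        for i in range(dom.m):
            lo = max(a, dom.barriers[i])
            hi = min(b, dom.barriers[i + 1])
            if hi <= lo:
                continue
            x1 = lo - dom.barriers[i]
            x2 = hi - dom.barriers[i]
            al = alphas[:, i]
            A, B = self.coeffs[:, i, 0], self.coeffs[:, i, 1]
            with np.errstate(invalid="ignore", divide="ignore"):
                seg = (A * (np.sin(al * x2) - np.sin(al * x1))
                       - B * (np.cos(al * x2) - np.cos(al * x1))) / al
            # α = 0 (constant mode): ∫ A dξ
            zero = al == 0
            seg[zero] = A[zero] * (x2 - x1)
            out += seg
        return out


def steady_density(domain: Domain1D) -> float:
    """Long-time uniform density 1/(b_m − b_0) (1/µm)."""
    return 1.0 / domain.total_length


def _propagate(domain: Domain1D, lam: np.ndarray, renormalize: bool = True):
    """Propagate boundary data (u, φ=Du') from the sealed left end across all
    compartments at each λ.  Returns the right-end flux residual φ(b_m)
    (+ κ_m u(b_m) for a permeable right end) — the characteristic function.

    ``renormalize`` rescales (u, φ) to unit norm after each compartment with a
    strictly positive factor (sign-preserving) to prevent overflow at large λ.
    """
    lam = np.asarray(lam, dtype=float)
    u = np.ones_like(lam)
    phi = np.zeros_like(lam)
    for i in range(domain.m):
        D = domain.diffusivities[i]
        L = domain.lengths[i]
        al = np.sqrt(lam / D)
        c, s = np.cos(al * L), np.sin(al * L)
        Dal = D * al
        u, phi = u * c + phi * s / Dal, -u * Dal * s + phi * c
        if i < domain.m - 1:
            kappa = domain.permeabilities[i + 1]
            # jump condition: flux continuous, u_R = u_L + φ/κ
            u = u + phi / kappa
        if renormalize:
            r = np.hypot(u, phi)
            r = np.where(r > 0, r, 1.0)
            u, phi = u / r, phi / r
    return phi + domain.permeabilities[-1] * u


def characteristic_function(domain: Domain1D, lam):
    """Characteristic function F(λ*) whose sign changes at eigenvalues.

    Requires λ* > 0 (λ = 0 is the analytic constant mode, never searched).
    Internal impermeable barriers decouple the domain; F is then the product
    of the sub-domain characteristic functions, so its zero set is the union
    of the sealed sub-spectra.
    """
    lam = np.asarray(lam, dtype=float)
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)
    if np.any(lam <= 0):
        raise DomainError("characteristic function defined for positive λ only")
    F = np.ones_like(lam)
    for sub in _split_impermeable(domain):
        F = F * _propagate(sub, lam)
    return float(F[0]) if scalar else F


def _split_impermeable(domain: Domain1D) -> list[Domain1D]:
    """Split a domain at internal κ = 0 barriers into decoupled sub-domains."""
    cuts = [0] + [i for i in range(1, domain.m)
                  if domain.permeabilities[i] == 0] + [domain.m]
    if len(cuts) == 2:
        return [domain]
    subs = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        b = domain.barriers[lo:hi + 1]
        d = domain.diffusivities[lo:hi]
        k = domain.permeabilities[lo:hi + 1].copy()
        k[0] = k[-1] = 0.0
        subs.append(Domain1D(b, d, k))
    return subs


def _mode_coeffs(domain: Domain1D, lam: float) -> np.ndarray:
    """Unnormalized (A, B) per compartment for a single eigenvalue λ > 0."""
    m = domain.m
    coeffs = np.empty((m, 2))
    u, phi = 1.0, 0.0
    for i in range(m):
        D = domain.diffusivities[i]
        L = domain.lengths[i]
        al = np.sqrt(lam / D)
        coeffs[i] = (u, phi / (D * al))
        c, s = np.cos(al * L), np.sin(al * L)
        u, phi = u * c + phi * s / (D * al), -u * D * al * s + phi * c
        if i < m - 1:
            kappa = domain.permeabilities[i + 1]
            if kappa == 0:
                # decoupled: mode lives left of the cut only
                coeffs[i + 1:] = 0.0
                return coeffs
            u = u + phi / kappa
    return coeffs


def _norm_sq(domain: Domain1D, lam: float, coeffs: np.ndarray) -> float:
    """∫ u² dx in closed form for piecewise A cos + B sin."""
    total = 0.0
    for i in range(domain.m):
        A, B = coeffs[i]
        L = domain.lengths[i]
        if lam == 0:
            total += A * A * L
            continue
        al = np.sqrt(lam / domain.diffusivities[i])
        s2 = np.sin(2 * al * L)
        total += (A * A * (L / 2 + s2 / (4 * al))
                  + B * B * (L / 2 - s2 / (4 * al))
                  + A * B * np.sin(al * L) ** 2 / al)
    return total


def _find_roots_connected(domain: Domain1D, lam_max: float,
                          scan_points: int) -> np.ndarray:
    """Bracketed roots of F on (0, lam_max] for a domain with all internal
    κ > 0.  Scan uniform in sqrt(λ) (root density is near-uniform there)."""
    s = np.linspace(0.0, np.sqrt(lam_max), scan_points + 1)[1:]
    lam_grid = s * s
    F = _propagate(domain, lam_grid)
    roots = []
    sign = np.sign(F)
    f_scalar = lambda lam: float(_propagate(domain, np.array([lam]))[0])
    for k in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(brentq(f_scalar, lam_grid[k], lam_grid[k + 1],
                            rtol=1e-14, xtol=1e-300))
    for k in np.nonzero(F == 0)[0]:
        roots.append(float(lam_grid[k]))
    roots = np.unique(np.asarray(roots))
    _warn_missed_roots(domain, roots)
    return roots


def _warn_missed_roots(domain: Domain1D, roots: np.ndarray) -> None:
    """Weyl-density check: the mean eigenvalue spacing in sqrt(λ) is
    asymptotically π / Σ(L_i / sqrt(D_i)); a gap much larger than that
    suggests a root was stepped over (e.g. a near-double root inside one
    scan cell)."""
    if roots.size < 4:
        return
    expected = np.pi / float(np.sum(domain.lengths
                                    / np.sqrt(domain.diffusivities)))
    gaps = np.diff(np.sqrt(roots))
    if np.max(gaps) > 3.0 * expected:
        k = int(np.argmax(gaps))
        warnings.warn(
            f"possible missed eigenvalue between λ={roots[k]:.6g} and "
            f"λ={roots[k + 1]:.6g} (sqrt-gap {gaps[k]:.3g} vs expected "
            f"{expected:.3g}); increase scan_points",
            RuntimeWarning,
        )


def find_eigenvalues(domain: Domain1D, lam_max: float = 500.0,
                     n_max: int = 1000, scan_points: int = 100_000
                     ) -> EigenSpectrum:
    """Locate the spectrum on (0, λ*_max], prepend the analytic λ = 0 constant
    mode, reconstruct and normalize every eigenmode.

    Roots are bracketed on a grid uniform in sqrt(λ*) and refined to relative
    tolerance ~1e-12; the result is truncated to ``n_max`` modes.
    """
    if lam_max <= 0:
        raise DomainError("lam_max must be positive")
    subs = _split_impermeable(domain)
    entries = []  # (lam, coeffs over full domain)
    m = domain.m
    comp_offset = 0
    sub_points = max(1000, scan_points // len(subs))
    for sub in subs:
        lam0_coeffs = np.zeros((m, 2))
        lam0_coeffs[comp_offset:comp_offset + sub.m, 0] = 1.0
        entries.append((0.0, lam0_coeffs))
        for lam in _find_roots_connected(sub, lam_max, sub_points):
            c = np.zeros((m, 2))
            c[comp_offset:comp_offset + sub.m] = _mode_coeffs(sub, lam)
            entries.append((lam, c))
        comp_offset += sub.m
    entries.sort(key=lambda e: e[0])
    entries = entries[:n_max]
    eigenvalues = np.array([e[0] for e in entries])
    coeffs = np.stack([e[1] for e in entries])
    # normalize each mode over the full domain
    for n in range(eigenvalues.size):
        nrm = 0.0
        off = 0
        for sub in subs:
            nrm += _norm_sq(sub, eigenvalues[n], coeffs[n, off:off + sub.m])
            off += sub.m
        coeffs[n] /= np.sqrt(nrm)
    return EigenSpectrum(domain, eigenvalues, coeffs, lam_max, scan_points)


def eigenmode_eval(spectrum: EigenSpectrum, n: int, x) -> np.ndarray | float:
    """Evaluate normalized mode ν_n at x (µm); returns 1/sqrt(µm) values."""
    x_arr = np.asarray(x, dtype=float)
    vals = spectrum.eval_matrix(np.atleast_1d(x_arr))[n]
    return float(vals[0]) if x_arr.ndim == 0 else vals


def _sum_modes(spectrum: EigenSpectrum, x: np.ndarray, t: float,
               weights: np.ndarray, provenance: str) -> DensityField:
    x = np.asarray(x, dtype=float)
    decay = np.exp(-spectrum.eigenvalues * t)
    V = spectrum.eval_matrix(x)
    U = (weights * decay) @ V
    return DensityField(x, U, t, provenance)


def propagator_delta(spectrum: EigenSpectrum, x, t: float, x0: float
                     ) -> DensityField:
    """Density U(x, t) for a delta release at x0:
    Σ_n exp(−λ_n t) ν_n(x) ν_n(x0)."""
    w = spectrum.eval_matrix(np.array([x0]))[:, 0]
    return _sum_modes(spectrum, x, t, w, "eigen")


def propagator_uniform(spectrum: EigenSpectrum, x, t: float,
                       interval: tuple[float, float]) -> DensityField:
    """Density U(x, t) for a uniform release on [a, b]: the delta solution
    averaged over the interval, i.e. weights (1/(b−a)) ∫_a^b ν_n dx'."""
    a, b = interval
    if a == b:
        return propagator_delta(spectrum, x, t, a)
    w = spectrum.mode_integrals(a, b) / (b - a)
    return _sum_modes(spectrum, x, t, w, "eigen")
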