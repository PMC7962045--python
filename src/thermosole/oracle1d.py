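"""Closed-form 1-D multilayer steady Pennes solution.

Verification oracle for the 3-D finite-volume solver on laterally uniform
configurations.  Within each layer the steady equation
``k T'' + rho_b C_pb omega (T_b - T) + Q_met = 0`` has the closed form

* perfused (omega > 0):  T(t) = T_eq + A exp(-m t) + B exp(-m (L - t))
  with m = sqrt(rho_b C_pb omega / k) and T_eq = T_b + Q_met/(rho_b C_pb omega)
* non-perfused:          T(t) = -Q_met t^2 / (2 k) + A t + B

where t is the local coordinate from the layer top.  The decaying
exponential basis keeps every basis value in (0, 1] regardless of m*L, so
thick, strongly perfused layers cannot overflow.  Coefficients follow from
temperature/flux continuity at interfaces (with optional contact-resistance
jumps) and the outer boundary conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DomainGrid
from .materials import DEFAULT_BLOOD, BloodProps, LayerSpec
from .solver import BoundarySpec, TemperatureField

__all__ = ["Oracle1DSolution", "solve_1d", "compare_to_oracle"]


@dataclass
class Oracle1DSolution:
    """Per-layer closed-form coefficients; callable at any depth z."""

    layers: list[LayerSpec]
    blood: BloodProps
    bc: BoundarySpec
    coeffs: np.ndarray  # (n_layers, 2) -> (A_i, B_i)
    z_interfaces: np.ndarray  # n_layers + 1 edges from z = 0 (top)
    contact_resistances: np.ndarray  # n_layers - 1

    def _layer_index(self, z: np.ndarray) -> np.ndarray:
        i = np.searchsorted(self.z_interfaces, z, side="right") - 1
        return np.clip(i, 0, len(self.layers) - 1)

    def _params(self, i: int):
        mat = self.layers[i].material
        k = mat.thermal_conductivity
        if mat.is_perfused:
            pc = self.blood.volumetric_heat_capacity * mat.perfusion_rate
            m = np.sqrt(pc / k)
            teq = mat.equilibrium_temperature(self.blood)
            return k, m, teq
        return k, None, None

    def temperature(self, z) -> np.ndarray:
        scalar = np.ndim(z) == 0
        z = np.atleast_1d(np.asarray(z, dtype=float))
        out = np.empty_like(z)
        li = self._layer_index(z)
        for i in range(len(self.layers)):
            sel = li == i
            if not sel.any():
                continue
            t = z[sel] - self.z_interfaces[i]
            length = self.layers[i].thickness
            a, b = self.coeffs[i]
            k, m, teq = self._params(i)
            if m is not None:
                out[sel] = teq + a * np.exp(-m * t) + b * np.exp(-m * (length - t))
            else:
                q = self.layers[i].material.metabolic_heat
                out[sel] = -q * t**2 / (2 * k) + a * t + b
        return out[0] if scalar else out

    def flux(self, z) -> np.ndarray:
        """Downward conductive heat flux -k dT/dz, W/m^2."""
        scalar = np.ndim(z) == 0
        z = np.atleast_1d(np.asarray(z, dtype=float))
        out = np.empty_like(z)
        li = self._layer_index(z)
        for i in range(len(self.layers)):
            sel = li == i
            if not sel.any():
                continue
            t = z[sel] - self.z_interfaces[i]
            length = self.layers[i].thickness
            a, b = self.coeffs[i]
            k, m, _ = self._params(i)
            if m is not None:
                dt = -m * a * np.exp(-m * t) + m * b * np.exp(-m * (length - t))
            else:
                q = self.layers[i].material.metabolic_heat
                dt = -q * t / k + a
            out[sel] = -k * dt
        return out[0] if scalar else out

    def __call__(self, z) -> np.ndarray:
        return self.temperature(z)

    def interface_values(self, i: int) -> tuple[float, float, float, float]:
        """Exact (T_above, T_below, q_above, q_below) at interface ``i``.

        Interface ``i`` separates layer i from layer i+1; evaluation is at
        the interface itself from each layer's closed form (the pointwise
        ``flux`` at z +/- eps differs by the distributed source over eps).
        """
        la, lb = self.layers[i], self.layers[i + 1]
        va, da = _basis(la, self.blood, la.thickness)
        pa, pda = _particular(la, self.blood, la.thickness)
        vb, db = _basis(lb, self.blood, 0.0)
        pb, pdb = _particular(lb, self.blood, 0.0)
        ca, cb = self.coeffs[i], self.coeffs[i + 1]
        t_above = float(ca @ va + pa)
        t_below = float(cb @ vb + pb)
        q_above = float(-la.material.thermal_conductivity * (ca @ da + pda))
        q_below = float(-lb.material.thermal_conductivity * (cb @ db + pdb))
        return t_above, t_below, q_above, q_below


def _basis(layer: LayerSpec, blood: BloodProps, t: float):
    """(value, derivative) rows of the two basis functions at local coord t."""
    mat = layer.material
    k = mat.thermal_conductivity
    length = layer.thickness
    if mat.is_perfused:
        m = np.sqrt(blood.volumetric_heat_capacity * mat.perfusion_rate / k)
        va = np.exp(-m * t)
        vb = np.exp(-m * (length - t))
        return np.array([va, vb]), np.array([-m * va, m * vb])
    return np.array([t, 1.0]), np.array([1.0, 0.0])


def _particular(layer: LayerSpec, blood: BloodProps, t: float):
    """(value, derivative) of the particular solution at local coord t."""
    mat = layer.material
    if mat.is_perfused:
        return mat.equilibrium_temperature(blood), 0.0
    k = mat.thermal_conductivity
    q = mat.metabolic_heat
    return -q * t**2 / (2 * k), -q * t / k


def solve_1d(
    layers: list[LayerSpec],
    blood: BloodProps = DEFAULT_BLOOD,
    bc: BoundarySpec | None = None,
    sock_after_layer: int | None = None,
) -> Oracle1DSolution:
    """Solve the 1-D stack (ordered top to bottom, z downward from 0).

    ``sock_after_layer`` names the interface (between that layer index and
    the next) carrying ``bc.sock_resistance``.  Raises on a degenerate
    configuration with no temperature anchor (singular interface system).
    """
    bc = bc or BoundarySpec()
    if not layers:
        raise ValueError("at least one layer required")
    n = len(layers)
    if bc.sock_resistance > 0 and sock_after_layer is None and n > 1:
        raise ValueError(
            "sock_resistance > 0: specify sock_after_layer for the 1-D stack"
        )
    anchored = bc.floor_h > 0 or bc.top == "fixed" or any(
        sp.material.is_perfused for sp in layers
    )
    if not anchored:
        raise ValueError(
            "singular 1-D configuration: all-adiabatic with zero perfusion"
        )

    resist = np.zeros(max(n - 1, 0))
    if sock_after_layer is not None and bc.sock_resistance > 0:
        resist[sock_after_layer] = bc.sock_resistance

    z_if = np.concatenate([[0.0], np.cumsum([sp.thickness for sp in layers])])
    a_mat = np.zeros((2 * n, 2 * n))
    rhs = np.zeros(2 * n)
    row = 0

    def flux_row(i: int, t: float):
        k = layers[i].material.thermal_conductivity
        v, d = _basis(layers[i], blood, t)
        pv, pd = _particular(layers[i], blood, t)
        return -k * d, -k * pd  # coefficients, particular flux

    # top boundary
    if bc.top == "fixed":
        v, _ = _basis(layers[0], blood, 0.0)
        pv, _ = _particular(layers[0], blood, 0.0)
        a_mat[row, 0:2] = v
        rhs[row] = bc.top_T - pv
    else:  # adiabatic
        c, pflux = flux_row(0, 0.0)
        a_mat[row, 0:2] = c
        rhs[row] = -pflux
    row += 1

    # interfaces: flux continuity and temperature jump across contact R
    for i in range(n - 1):
        li, lj = layers[i], layers[i + 1]
        ci, pfi = flux_row(i, li.thickness)
        cj, pfj = flux_row(i + 1, 0.0)
        a_mat[row, 2 * i : 2 * i + 2] = ci
        a_mat[row, 2 * (i + 1) : 2 * (i + 1) + 2] = -cj
        rhs[row] = pfj - pfi
        row += 1
        vi, _ = _basis(li, blood, li.thickness)
        pvi, _ = _particular(li, blood, li.thickness)
        vj, _ = _basis(lj, blood, 0.0)
        pvj, _ = _particular(lj, blood, 0.0)
        # T_i(L) - T_j(0) = R * q_i(L)
        a_mat[row, 2 * i : 2 * i + 2] = vi - resist[i] * ci
        a_mat[row, 2 * (i + 1) : 2 * (i + 1) + 2] = -vj
        rhs[row] = pvj - pvi + resist[i] * pfi
        row += 1

    # bottom boundary: Robin q = h (T - T_env); h = 0 reduces to adiabatic
    i = n - 1
    length = layers[i].thickness
    c, pflux = flux_row(i, length)
    v, _ = _basis(layers[i], blood, length)
    pv, _ = _particular(layers[i], blood, length)
    a_mat[row, 2 * i : 2 * i + 2] = c - bc.floor_h * v
    rhs[row] = bc.floor_h * (pv - bc.floor_T_env) - pflux

    # row equilibration + iterative refinement: the interface system mixes
    # O(1) basis values with O(k/L) flux rows, and plain LU leaves ~1e-7
    # relative error at interfaces; two refinement steps restore continuity
    # to linear-algebra round-off.
    scale = np.max(np.abs(a_mat), axis=1)
    if (scale == 0).any():
        raise ValueError("singular 1-D interface system (zero row)")
    a_s = a_mat / scale[:, None]
    b_s = rhs / scale
    try:
        x = np.linalg.solve(a_s, b_s)
        for _ in range(2):
            x += np.linalg.solve(a_s, b_s - a_s @ x)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular 1-D interface system: {exc}") from exc
    coeffs = x.reshape(n, 2)
    return Oracle1DSolution(
        layers=list(layers),
        blood=blood,
        bc=bc,
        coeffs=coeffs,
        z_interfaces=z_if,
        contact_resistances=resist,
    )


def compare_to_oracle(
    field: TemperatureField,
    grid: DomainGrid,
    oracle: Oracle1DSolution,
    column: tuple[float, float] | None = None,
) -> float:
    """Max |T_3D(x, y, z) - T_1D(z)| over a vertical column of cell centers.

    Requires a laterally uniform configuration whose layer stack matches the
    oracle's (names and thicknesses), otherwise raises.
    """
    g_stack = [(sp.material.name, sp.thickness) for sp in grid.layers]
    o_stack = [(sp.material.name, sp.thickness) for sp in oracle.layers]
    if len(g_stack) != len(o_stack) or any(
        gn != on or abs(gt - ot) > 1e-12
        for (gn, gt), (on, ot) in zip(g_stack, o_stack)
    ):
        raise ValueError("grid and oracle layer stacks do not match")

    if column is None:
        column = (grid.footprint[0] / 2, grid.footprint[1] / 2)
    ix = int(np.argmin(np.abs(grid.x_centers - column[0])))
    iy = int(np.argmin(np.abs(grid.y_centers - column[1])))
    act = grid.active[ix, iy, :]
    zc = grid.z_centers[act]
    t3d = field.T[ix, iy, act]
    return float(np.max(np.abs(t3d - oracle.temperature(zc))))
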