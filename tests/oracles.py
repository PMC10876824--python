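"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the kinetic model
is integrated numerically from the ODE definition, the grid-search fitter
profiles the only nonlinear parameter over a dense grid with a bounded
linear solve, Gaussian blur is re-done with explicit separable kernels,
and dilation is re-done as a breadth-first search on the voxel lattice.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import nnls


def ode_curve(params, times: np.ndarray) -> np.ndarray:
    """High-accuracy numerical integration of the three-phase ODE."""
    t_a, t_b, k_l, k_g, c0 = params.t_a, params.t_b, params.k_l, params.k_g, params.c0
    prod = 2.0 * params.alpha * params.cmro2
    dur = t_b - t_a

    def excess(t: float) -> float:
        if t < t_a:
            return 0.0
        if t <= t_b:
            return t - t_a
        return dur * np.exp(-k_l * (t - t_b))

    def rhs(t, y):
        u = 1.0 if t_a <= t <= t_b else 0.0
        return [prod * u + k_g * excess(t) - k_l * (y[0] - c0)]

    sol = solve_ivp(rhs, (0.0, float(times[-1])), [c0], t_eval=times,
                    rtol=1e-11, atol=1e-13, max_step=0.25)
    return sol.y[0]


def grid_search_designs(times: np.ndarray, t_a: float, t_b: float, alpha: float,
                        kl_grid: np.ndarray) -> list:
    """Design matrices [1, production response, gain response] per k_l node.

    The basis responses are obtained by numerically integrating the ODE for
    unit production and unit gain, so the whole oracle never touches the
    closed-form implementation under test.
    """

    class _P:
        def __init__(self, cmro2, k_l, k_g):
            self.cmro2, self.k_l, self.k_g = cmro2, k_l, k_g
            self.alpha, self.c0, self.t_a, self.t_b = alpha, 1.0, t_a, t_b

    designs = []
    ones = np.ones_like(times)
    for kl in kl_grid:
        resp_prod = ode_curve(_P(1.0 / (2.0 * alpha), kl, 0.0), times) - 1.0
        resp_gain = ode_curve(_P(0.0, kl, 1.0), times) - 1.0
        designs.append((kl, np.column_stack([ones, resp_prod, resp_gain])))
    return designs


def grid_search_fit(values: np.ndarray, designs: list, alpha: float) -> dict:
    """Brute-force fit: profile k_l over the grid, NNLS for the linear part."""
    best = None
    for kl, design in designs:
        coef, rnorm = nnls(design, values)
        if best is None or rnorm < best["residual"]:
            best = {"residual": rnorm, "c0": coef[0],
                    "cmro2": coef[1] / (2.0 * alpha), "k_g": coef[2], "k_l": kl}
    return best


def gaussian_blur_explicit(data: np.ndarray, fwhm_mm: float,
                           voxel_size_mm, truncate: float = 4.0) -> np.ndarray:
    """Separable Gaussian convolution with explicit kernels (zero padding)."""
    out = np.asarray(data, dtype=float)
    for axis, vox in enumerate(voxel_size_mm):
        sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vox
        radius = int(truncate * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        padded = np.moveaxis(out, axis, -1)
        shape = padded.shape
        flat = padded.reshape(-1, shape[-1])
        conv = np.empty_like(flat)
        for i in range(flat.shape[0]):
            conv[i] = np.convolve(np.pad(flat[i], radius), kernel, mode="valid")
        out = np.moveaxis(conv.reshape(shape), -1, axis)
    return out


def dilate_bfs(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Breadth-first 6-neighbourhood dilation on the voxel lattice."""
    from collections import deque

    mask = np.asarray(mask, dtype=bool)
    dist = np.full(mask.shape, -1, dtype=int)
    queue = deque()
    for idx in np.argwhere(mask):
        dist[tuple(idx)] = 0
        queue.append(tuple(idx))
    neighbours = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while queue:
        pos = queue.popleft()
        if dist[pos] >= iterations:
            continue
        for d in neighbours:
            nb = tuple(p + q for p, q in zip(pos, d))
            if all(0 <= n < s for n, s in zip(nb, mask.shape)) and dist[nb] < 0:
                dist[nb] = dist[pos] + 1
                queue.append(nb)
    return dist >= 0


def t4_tail_closed_form(t: float) -> float:
    """Upper-tail probability of Student's t with 4 degrees of freedom.

    Closed form of the df=4 CDF: F(t) = 1/2 + (3/4)·(sinθ − sin³θ/3) with
    tanθ = t/2; the tail is 1 − F(t).
    """
    theta = np.arctan(t / 2.0)
    cdf = 0.5 + 0.75 * (np.sin(theta) - np.sin(theta) ** 3 / 3.0)
    return 1.0 - cdf
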