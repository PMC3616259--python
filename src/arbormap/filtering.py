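"""Coherence-enhancing anisotropic diffusion for tubular structures.

The morphology channel of a confocal stack shows thin, branched, roughly
cylindrical neurites over a noisy background. Linear smoothing would blur
them away; instead we diffuse *along* the local structure orientation and
much less across it, which smooths intensity along each neurite, suppresses
background speckle, and can bridge small axial gaps left by uneven labeling.

The scheme: at each voxel the structure tensor of the σ-presmoothed image is
averaged over a neighborhood of scale ρ and eigen-decomposed. The diffusion
tensor shares the eigenvectors; the eigen-direction of least intensity
variation (the neurite axis) gets diffusivity 1, the others get a diffusivity
that falls from 1 in flat regions to ``1/along_to_across_ratio`` at strong
edges. With ``along_to_across_ratio == 1`` the tensor reduces to the identity
and the filter is exactly linear (heat-equation) diffusion.

The update is an explicit conservative finite-volume step: fluxes are
evaluated on voxel faces and differenced, with zero flux through the image
boundary (Neumann), so the total intensity is conserved to machine precision
at every iteration. All gradients use physical μm spacing, so behavior is
consistent on anisotropic voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import ImageStack
from .segmentation import SegmentationMask, SegmentationParams, segment

__all__ = ["DiffusionParams", "anisotropic_diffuse", "filter_segment_rounds"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the anisotropic diffusion filter.

    Attributes
    ----------
    n_iterations : int
        Explicit time steps (default 10).
    time_step : float or None
        Step size; ``None`` selects 0.9× the explicit-scheme 3D stability
        bound ``1 / (2 Σ_a h_a^-2)`` for the given voxel spacing.
    gradient_scale_um : float or None
        Gaussian presmoothing σ (μm) for gradient estimation; ``None`` means
        one lateral voxel.
    tensor_scale_um : float or None
        Gaussian averaging ρ (μm) of the structure tensor; ``None`` means
        four lateral voxels.
    edge_contrast : float
        Gray-level contrast (per gradient scale) separating "structure" from
        "flat"; gradients well above ``edge_contrast / gradient_scale`` see
        the reduced cross-structure diffusivity.
    along_to_across_ratio : float
        Ratio (≥ 1) of diffusivity along the structure axis to the diffusivity
        across it at a strong edge. 1 forces isotropic linear diffusion.
    """

    n_iterations: int = 10
    time_step: float | None = None
    gradient_scale_um: float | None = None
    tensor_scale_um: float | None = None
    edge_contrast: float = 10.0
    along_to_across_ratio: float = 10.0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.time_step is not None and self.time_step <= 0:
            raise ValueError("time_step must be positive")
        for name in ("gradient_scale_um", "tensor_scale_um"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.edge_contrast <= 0:
            raise ValueError("edge_contrast must be positive")
        if self.along_to_across_ratio < 1:
            raise ValueError("along_to_across_ratio must be >= 1")


def stability_bound(spacing_zyx: tuple[float, float, float]) -> float:
    """Largest stable explicit time step for unit diffusivity, 3D."""
    return 1.0 / (2.0 * sum(1.0 / h ** 2 for h in spacing_zyx))


def _diffusion_tensor(u: np.ndarray, spacing: tuple[float, float, float],
                      params: DiffusionParams) -> np.ndarray:
    """Per-voxel 3x3 diffusion tensor from the smoothed structure tensor."""
    hz, hy, hx = spacing
    sig = params.gradient_scale_um if params.gradient_scale_um is not None else hx
    rho = params.tensor_scale_um if params.tensor_scale_um is not None else 4 * hx
    sig_vox = (sig / hz, sig / hy, sig / hx)
    rho_vox = (rho / hz, rho / hy, rho / hx)

    us = gaussian_filter(u, sig_vox, mode="nearest")
    grads = np.gradient(us, hz, hy, hx)
    # structure tensor, ρ-averaged
    J = np.empty(u.shape + (3, 3))
    for a in range(3):
        for b in range(a, 3):
            Jab = gaussian_filter(grads[a] * grads[b], rho_vox, mode="nearest")
            J[..., a, b] = Jab
            J[..., b, a] = Jab

    evals, evecs = np.linalg.eigh(J)  # ascending; evals[...,0] = along-axis
    r_inv = 1.0 / params.along_to_across_ratio
    # contrast scale: gray-level change `edge_contrast` over one gradient scale
    lam_c = (params.edge_contrast / sig) ** 2
    d = r_inv + (1.0 - r_inv) * np.exp(-np.maximum(evals, 0.0) / lam_c)
    d[..., 0] = 1.0  # full diffusivity along the structure axis
    # D = V diag(d) V^T
    D = np.einsum("...ik,...k,...jk->...ij", evecs, d, evecs)
    return D


def _divergence_step(u: np.ndarray, D: np.ndarray,
                     spacing: tuple[float, float, float]) -> np.ndarray:
    """div(D grad u) with face-centered fluxes, zero-flux boundaries.

    Face fluxes telescope exactly, so the voxel sum of the returned update is
    zero to rounding.
    """
    h = spacing
    grads = list(np.gradient(u, *spacing))  # central differences, for cross terms
    div = np.zeros_like(u)
    for a in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(None, -1)
        sl_hi[a] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        # gradient components on the face between i and i+1 along axis a
        flux = np.zeros_like(u[sl_lo])
        for b in range(3):
            Dab_face = 0.5 * (D[sl_lo + (a, b)] + D[sl_hi + (a, b)])
            if b == a:
                g_face = (u[sl_hi] - u[sl_lo]) / h[a]
            else:
                g_face = 0.5 * (grads[b][sl_lo] + grads[b][sl_hi])
            flux += Dab_face * g_face
        div[sl_lo] += flux / h[a]
        div[sl_hi] -= flux / h[a]
    return div


def anisotropic_diffuse(stack: ImageStack, params: DiffusionParams | None = None,
                        ) -> ImageStack:
    """Filter a stack with coherence-enhancing anisotropic diffusion.

    Arithmetic is done in float64; the result is re-quantized to the stack's
    bit range only at output. Shape and calibration are preserved.
    """
    params = params or DiffusionParams()
    spacing = stack.geometry.spacing_zyx
    dt = params.time_step if params.time_step is not None \
        else 0.9 * stability_bound(spacing)
    u = stack.voxels.astype(np.float64)
    for it in range(params.n_iterations):
        D = _diffusion_tensor(u, spacing, params)
        u += dt * _divergence_step(u, D, spacing)
    out = np.clip(np.rint(u), 0, stack.max_gray)
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    return stack.with_voxels(out.astype(dtype))


def diffuse_float(voxels: np.ndarray, spacing: tuple[float, float, float],
                  params: DiffusionParams, record_sums: list | None = None,
                  ) -> np.ndarray:
    """Float-valued diffusion without re-quantization.

    Exposed for numerical verification (conservation, linear-limit checks);
    ``record_sums``, if given, collects the voxel sum after every iteration.
    """
    dt = params.time_step if params.time_step is not None \
        else 0.9 * stability_bound(spacing)
    u = np.asarray(voxels, dtype=np.float64).copy()
    for _ in range(params.n_iterations):
        D = _diffusion_tensor(u, spacing, params)
        u += dt * _divergence_step(u, D, spacing)
        if record_sums is not None:
            record_sums.append(float(u.sum()))
    return u


def filter_segment_rounds(stack: ImageStack,
                          params: DiffusionParams | None = None,
                          seg_params: SegmentationParams | None = None,
                          n_rounds: int = 2,
                          intermediates: list | None = None,
                          ) -> SegmentationMask:
    """Alternate filtering and segmentation for ``n_rounds`` rounds.

    After each round the binary mask (scaled to 255) becomes the input to the
    next round's filter; repeated rounds consolidate genuine neurites while
    fragmenting and dropping small unrelated processes. ``intermediates``, if
    given, collects the per-round filtered stacks and masks for inspection.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    params = params or DiffusionParams()
    seg_params = seg_params or SegmentationParams()
    current = stack
    mask: SegmentationMask | None = None
    for rnd in range(n_rounds):
        filtered = anisotropic_diffuse(current, params)
        mask = segment(filtered, seg_params)
        log.info("round %d: threshold produced %d foreground voxels, %d components",
                 rnd + 1, int(mask.voxels.sum()), mask.n_components)
        if intermediates is not None:
            intermediates.append((filtered, mask))
        current = stack.with_voxels(
            (mask.voxels.astype(np.uint8)) * np.uint8(255))
    assert mask is not None
    return mask
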