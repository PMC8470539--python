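"""Image front end: discretize an RGB raster into a Potts state grid, render
synthetic multi-population tissue images, and inpaint hidden cell classes as
probability maps via clamped conditional sampling.

The grid uses an open-boundary 2-D lattice (an image has edges).  Cells are
classified by the mean RGB of the pixels inside them: below a brightness
threshold the cell is background (state 0), otherwise it takes the state of
the nearest reference color.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampler import PottsParameters, SamplerOptions, conditional_marginals
from .topology import NetworkTopology, build_lattice

__all__ = [
    "ColorClassDef",
    "StateGrid",
    "default_colors",
    "discretize_image",
    "render_state_grid",
    "generate_synthetic_tissue",
    "infer_missing_states",
    "InferenceResult",
    "coupling_report",
]


@dataclass
class ColorClassDef:
    """Ordered color classes: (state index, label, reference RGB).

    The default four classes are background/black, green, red, blue — the
    standard ordering for multi-marker fluorescence grids.  A cell whose mean
    brightness falls below ``brightness_threshold`` (0-255 scale) is assigned
    to the background class regardless of hue.
    """

    classes: list = field(default_factory=lambda: [
        (0, "black", (0, 0, 0)),
        (1, "green", (0, 255, 0)),
        (2, "red", (255, 0, 0)),
        (3, "blue", (0, 0, 255)),
    ])
    brightness_threshold: float = 40.0

    def __post_init__(self):
        idx = [c[0] for c in self.classes]
        if idx != list(range(len(self.classes))):
            raise ValueError("state indices must be contiguous from 0")

    @property
    def n_states(self) -> int:
        return len(self.classes)

    @property
    def labels(self) -> list:
        return [c[1] for c in self.classes]

    @property
    def reference_rgb(self) -> np.ndarray:
        return np.array([c[2] for c in self.classes], dtype=float)


def default_colors() -> ColorClassDef:
    return ColorClassDef()


@dataclass
class StateGrid:
    """R x C state matrix with its color definition and provenance."""

    states: np.ndarray
    colors: ColorClassDef
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2:
            raise ValueError("state grid must be 2-D")
        if self.states.size and (self.states.min() < 0
                                 or self.states.max() >= self.colors.n_states):
            raise ValueError("state out of range for the color definition")

    @property
    def shape(self):
        return self.states.shape

    def topology(self) -> NetworkTopology:
        return build_lattice(self.states.shape, periodic=False)

    def flat(self) -> np.ndarray:
        return self.states.ravel()


def _as_rgb_array(image) -> np.ndarray:
    if hasattr(image, "convert"):  # PIL image
        image = np.asarray(image.convert("RGB"))
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("image must be an RGB raster (H, W, 3)")
    return image[:, :, :3]


def discretize_image(image, grid_shape, colors: ColorClassDef | None = None) -> StateGrid:
    """Average the pixels inside each grid cell and classify the mean color.

    Deterministic: brightness guard first, then nearest reference color in
    RGB distance.
    """
    colors = colors or default_colors()
    arr = _as_rgb_array(image)
    H, W = arr.shape[:2]
    R, C = grid_shape
    if R > H or C > W:
        raise ValueError("grid larger than image")
    # cell boundaries by even pixel partition
    rows = np.linspace(0, H, R + 1).astype(int)
    cols = np.linspace(0, W, C + 1).astype(int)
    means = np.zeros((R, C, 3))
    for i in range(R):
        for j in range(C):
            cell = arr[rows[i]:rows[i + 1], cols[j]:cols[j + 1]]
            means[i, j] = cell.reshape(-1, 3).mean(axis=0)
    refs = colors.reference_rgb
    d2 = ((means[:, :, None, :] - refs[None, None, :, :]) ** 2).sum(axis=3)
    states = d2.argmin(axis=2)
    brightness = means.mean(axis=2)
    states[brightness < colors.brightness_threshold] = 0
    return StateGrid(states=states, colors=colors,
                     metadata={"grid_shape": [R, C], "source": "discretize"})


def render_state_grid(grid: StateGrid, cell_px: int = 4,
                      noise_sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Render each cell as a solid reference-color block of ``cell_px``
    pixels, with optional additive Gaussian noise (0-255 scale), clipped to
    uint8."""
    rng = np.random.default_rng(seed)
    refs = grid.colors.reference_rgb
    img = refs[grid.states]                      # (R, C, 3)
    img = np.kron(img, np.ones((cell_px, cell_px, 1)))
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_synthetic_tissue(grid_shape=(24, 24), densities=(0.45, 0.25, 0.15, 0.15),
                              couplings: np.ndarray | None = None,
                              cell_px: int = 4, noise_sigma: float = 0.0,
                              seed: int = 0,
                              colors: ColorClassDef | None = None):
    """Synthetic multi-population tissue image with known ground truth.

    A ground-truth grid is drawn from a Potts model whose fields are set
    from the requested per-class densities.  The default couplings mimic a
    marker-colocalization pattern: the blue class mildly self-clusters, is
    attracted to the green class and repelled by the red one (the red class
    is otherwise nearly uncoupled), so hiding blue leaves genuine spatial
    evidence in the visible classes.  The grid is rendered as colored blocks
    with additive noise.  Returns ``(rgb_image, truth_grid)``.
    """
    from .simulators import generate_potts_ensemble

    colors = colors or default_colors()
    Q = colors.n_states
    densities = np.asarray(densities, dtype=float)
    if densities.sum() > 1 + 1e-9 or np.any(densities < 0):
        raise ValueError("densities must be nonnegative and sum to <= 1")
    densities = densities / densities.sum()
    topo = build_lattice(grid_shape, periodic=False)
    n = topo.n_nodes
    h = -n * np.log(densities)
    if couplings is None:
        # flat-convention couplings J_ij multiply densities, so a per-edge
        # energy g corresponds to J = g * n_links; kept below the ordering
        # transition, with the extra blue field balancing the attractions
        couplings = np.zeros((Q, Q))
        couplings[3, 3] = -0.3 * topo.n_links   # mild blue self-clustering
        couplings[1, 1] = -0.3 * topo.n_links   # mild green clustering
        couplings[1, 3] = couplings[3, 1] = -1.0 * topo.n_links  # blue near green
        couplings[2, 3] = couplings[3, 2] = +0.8 * topo.n_links  # blue avoids red
        couplings[1, 2] = couplings[2, 1] = +0.3 * topo.n_links  # red avoids green
        h[3] += 0.2 * n
    params = PottsParameters(h=h, J=[np.asarray(couplings, dtype=float)])
    ens = generate_potts_ensemble(params, topo, n_conf=1, seed=seed,
                                  method="metropolis")
    truth = StateGrid(states=ens.X[0].reshape(grid_shape), colors=colors,
                      metadata={"generator": "potts", "seed": seed,
                                "densities": densities.tolist()})
    img = render_state_grid(truth, cell_px=cell_px, noise_sigma=noise_sigma,
                            seed=seed + 1)
    return img, truth


@dataclass
class InferenceResult:
    """Per-hidden-state probability maps plus an optional truth score."""

    maps: dict                   # state -> (R, C) probability map
    hidden: tuple
    base_rates: dict             # state -> hidden-state base rate among free cells
    mean_true_probability: dict | None  # state -> mean map value at true cells


def infer_missing_states(grid: StateGrid, params: PottsParameters,
                         hidden, options: SamplerOptions | None = None,
                         background: int = 0, restrict_alphabet: bool = True,
                         truth: StateGrid | None = None) -> InferenceResult:
    """Predict where the hidden classes sit, given the visible ones.

    Cells observed in a hidden state or in the background state become free;
    all other cells are clamped at their observed state.  By default the free
    cells are restricted to the hidden states plus background (mirroring the
    visible-evidence protocol); ``restrict_alphabet=False`` frees the full
    alphabet.  The probability maps are empirical marginals over the stored
    clamped-Metropolis ensemble.
    """
    hidden = tuple(sorted(set(int(h) for h in hidden)))
    if not hidden:
        raise ValueError("nothing hidden")
    Q = params.n_states
    if any(h < 0 or h >= Q for h in hidden):
        raise ValueError("hidden state out of range")
    options = options or SamplerOptions(n_kept=1000, burn_in=500, stride=5)
    observed = grid.states.copy()
    # erase hidden states: they present as background to the observer
    observed[np.isin(observed, hidden)] = background
    free_mask = observed == background
    if not free_mask.any():
        raise ValueError("no free cells")
    if free_mask.all():
        raise ValueError("at least one visible cell is required")
    flat_obs = observed.ravel()
    clamped = {int(i): int(s) for i, s in enumerate(flat_obs)
               if not free_mask.ravel()[i]}
    alphabet = sorted(set(hidden) | {background}) if restrict_alphabet else list(range(Q))
    node_alphabets = {int(i): alphabet for i in np.flatnonzero(free_mask.ravel())}
    topo = grid.topology()
    marg = conditional_marginals(params, topo, clamped, options,
                                 node_alphabets=node_alphabets)
    R, C = grid.shape
    maps = {h: marg[:, h].reshape(R, C) for h in hidden}
    base_rates = {}
    mean_true = None
    if truth is not None:
        mean_true = {}
        for h in hidden:
            true_mask = (truth.states == h) & free_mask
            base_rates[h] = float(true_mask.sum() / free_mask.sum())
            if true_mask.any():
                mean_true[h] = float(maps[h][true_mask].mean())
            else:
                mean_true[h] = np.nan
    else:
        n_free = free_mask.sum()
        for h in hidden:
            base_rates[h] = float(maps[h][free_mask].sum() / n_free)
    return InferenceResult(maps=maps, hidden=hidden, base_rates=base_rates,
                           mean_true_probability=mean_true)


def coupling_report(params: PottsParameters, colors: ColorClassDef | None = None,
                    edge_class: int = 0) -> str:
    """Human-readable table of h and J with class labels.

    Sign convention: the Boltzmann weight is exp(-H), so a POSITIVE coupling
    is repulsion and a negative one attraction.  Absolute values are
    gauge-dependent; only relative comparisons are meaningful.
    """
    colors = colors or default_colors()
    labels = colors.labels[:params.n_states]
    J = params.J[edge_class]
    lines = [
        "Potts parameter report (exp(-H) convention: J > 0 repulsion, J < 0 attraction)",
        "WARNING: h and J have gauge freedom; interpret only relative values.",
        "",
        "fields h:",
    ]
    for lab, h in zip(labels, params.h):
        lines.append(f"  {lab:>8s}: {h: .3f}")
    lines.append("")
    lines.append("couplings J:")
    header = "          " + " ".join(f"{lab:>8s}" for lab in labels)
    lines.append(header)
    for i, lab in enumerate(labels):
        row = " ".join(f"{J[i, j]: 8.3f}" for j in range(len(labels)))
        lines.append(f"  {lab:>8s} {row}")
    off = J.copy()
    i, j = np.unravel_index(np.argmin(off), off.shape)
    if off[i, j] < 0:
        lines.append("")
        lines.append(
            f"strongest attraction: {labels[i]}-{labels[j]} (J = {off[i, j]:.3f})"
        )
    return "\n".join(lines)
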