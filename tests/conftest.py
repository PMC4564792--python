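import numpy as np
import pytest
from scipy import ndimage

from toothprop import PhantomConfig, generate_phantom, segment_teeth


def small_config(**overrides) -> PhantomConfig:
    """A 6-tooth phantom small enough for per-test runs."""
    kw = dict(
        shape=(96, 96, 40),
        n_teeth=6,
        arch_radius_vox=30.0,
        tooth_radius_vox=4.6,
        root_slice=6,
        crown_slice=34,
    )
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_config())


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(small_config(noise_sigma=0.0, contrast_gap=200.0))


@pytest.fixture(scope="session")
def default_runs():
    """Full-size default-condition runs (14 teeth, contrast gap 150 HU,
    noise sigma 20 HU) for three phantom seeds: (cfg, vol, gt, seeds, lab)."""
    runs = []
    for seed in (0, 1, 2):
        cfg = PhantomConfig(rng_seed=seed)
        vol, gt, seeds = generate_phantom(cfg)
        lab = segment_teeth(vol, seeds)
        runs.append((cfg, vol, gt, seeds, lab))
    return runs


# ---------------------------------------------------------------------------
# independent oracles


def flood_oracle(img, seeds, threshold, delta, connectivity, bbox=None):
    """Reference for seeded growing with a frozen mean: build the static
    admissibility mask vectorized, label it with scipy, keep the components
    holding seeds."""
    img = np.asarray(img, dtype=float)
    mean = np.mean([img[tuple(s)] for s in seeds])
    ok = (img >= threshold) & (np.abs(img - mean) < delta)
    if bbox is not None:
        sel = np.zeros(img.shape, dtype=bool)
        sel[bbox.slices()] = True
        ok &= sel
    order = {4: 1, 8: 2, 6: 1, 26: 3}[connectivity]
    labeled, _ = ndimage.label(ok, structure=ndimage.generate_binary_structure(img.ndim, order))
    ids = {int(labeled[tuple(s)]) for s in seeds} - {0}
    return np.isin(labeled, list(ids)) if ids else np.zeros(img.shape, bool)


def filled_seed_area(img, seeds, t):
    """Reference area measure: threshold, label (4-connectivity), keep seed
    components, fill their cavities with scipy, count."""
    labeled, _ = ndimage.label(img >= t, structure=ndimage.generate_binary_structure(2, 1))
    ids = {int(labeled[tuple(s)]) for s in seeds} - {0}
    if not ids:
        return 0
    return int(ndimage.binary_fill_holes(np.isin(labeled, list(ids))).sum())


def scan_threshold_oracle(img, prev_mask, seeds, t_lo, t_hi, tau, factor):
    """Exhaustive integer scan implementing the band-anchored threshold rule."""
    prev = int(prev_mask.sum())
    areas = {t: filled_seed_area(img, seeds, t) for t in range(t_lo, t_hi + 1)}
    lower, upper = (1 - tau) * prev, factor * prev
    feas = [t for t in range(t_lo, t_hi + 1) if areas[t] >= lower]
    if not feas:
        return None
    t_high = max(feas)
    not_over = [t for t in range(t_lo, t_hi + 1) if areas[t] <= upper]
    if not not_over or min(not_over) > t_high:
        return float(t_high)
    t_low = min(not_over)
    return float((t_low + t_high) // 2)
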