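"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hscquant import LobuleFieldSpec, generate_lobule_field
from hscquant.synthgen import tissue_mask_from_spec


def flood_fill_labels(binary: np.ndarray) -> tuple[np.ndarray, int]:
    """Brute-force 8-connected component labeling by BFS flood fill.

    Pure-Python oracle, independent of the labeling used by the package.
    """
    h, w = binary.shape
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for i in range(h):
        for j in range(w):
            if binary[i, j] and labels[i, j] == 0:
                current += 1
                labels[i, j] = current
                stack = [(i, j)]
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (
                                0 <= ny < h
                                and 0 <= nx < w
                                and binary[ny, nx]
                                and labels[ny, nx] == 0
                            ):
                                labels[ny, nx] = current
                                stack.append((ny, nx))
    return labels, current


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True if two label images induce the same partition of the foreground."""
    if (a > 0).sum() != (b > 0).sum() or not np.array_equal(a > 0, b > 0):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    # bijection: each a-label maps to exactly one b-label and vice versa
    a_labels = [p[0] for p in pairs]
    b_labels = [p[1] for p in pairs]
    return len(a_labels) == len(set(a_labels)) == len(set(b_labels))


@pytest.fixture
def small_field_spec() -> LobuleFieldSpec:
    """A quick-to-generate 150 x 150 µm noise-free field with 4 patches."""
    return LobuleFieldSpec(
        field_width_um=150.0,
        field_height_um=150.0,
        pixel_size_um=0.5,
        n_centrilobular_foci=1,
        n_patches=4,
        patch_radius_um_range=(3.0, 8.0),
        clustering_fraction=0.5,
        focus_radius_um=40.0,
        n_fibers=6,
        fiber_length_um=30.0,
        noise_sd=0.0,
        seed=42,
    )


@pytest.fixture
def small_field(small_field_spec):
    rf, cf, truth = generate_lobule_field(small_field_spec)
    tissue = tissue_mask_from_spec(small_field_spec)
    return rf, cf, truth, tissue
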