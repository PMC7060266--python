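"""Calibrate the 2x2x2 configuration weights of the surface-area estimator.

Digitized spheres with radii 5-50 voxels (voxel centres at (i+0.5), a voxel
is foreground when its centre lies within the sphere) are the calibration
family: for each sphere the local 2x2x2 foreground-count histogram is the
feature vector and 4*pi*r^2 the target area.  Weights for counts 1..7 are
obtained by non-negative least squares with the complement symmetry
w[c] = w[8-c] enforced, and frozen into depotmetry.morphometry.

Run from the repository root:

    python scripts/calibrate_surface_weights.py
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls


def digitized_sphere(radius: float) -> np.ndarray:
    n = int(np.ceil(2 * radius)) + 4
    c = n / 2.0
    zz, yy, xx = np.meshgrid(*[(np.arange(n) + 0.5) - c] * 3, indexing="ij")
    return zz * zz + yy * yy + xx * xx <= radius * radius


def config_counts(mask: np.ndarray) -> np.ndarray:
    p = np.pad(mask, 1, constant_values=False).astype(np.uint8)
    c = (
        p[:-1, :-1, :-1] + p[1:, :-1, :-1] + p[:-1, 1:, :-1] + p[:-1, :-1, 1:]
        + p[1:, 1:, :-1] + p[1:, :-1, 1:] + p[:-1, 1:, 1:] + p[1:, 1:, 1:]
    )
    return np.bincount(c.ravel(), minlength=9)[:9]


def main() -> None:
    radii = np.arange(5.0, 50.0 + 1e-9, 1.0)
    # symmetric parameterization: free weights for counts 1..4, mirrored onto 5..7
    rows, targets = [], []
    for r in radii:
        h = config_counts(digitized_sphere(r))
        feats = np.array([
            h[1] + h[7],
            h[2] + h[6],
            h[3] + h[5],
            h[4],
        ], dtype=float)
        rows.append(feats)
        targets.append(4.0 * np.pi * r * r)
    X = np.asarray(rows)
    y = np.asarray(targets)
    # weight rows by 1/target so relative (not absolute) errors are balanced
    w, _ = nnls(X / y[:, None], np.ones_like(y))
    weights = np.array([0.0, w[0], w[1], w[2], w[3], w[2], w[1], w[0], 0.0])
    rel_err = (X @ w - y) / y
    print("weights (counts 0..8):")
    print(np.array2string(weights, precision=8))
    print(f"max |relative error| over r=5..50: {np.abs(rel_err).max():.5f}")
    print(f"relative error at r=40: {rel_err[list(radii).index(40.0)]:.5f}")


if __name__ == "__main__":
    main()
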