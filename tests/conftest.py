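"""Shared fixtures: small seeded cohorts and a brute-force dCor oracle."""

import numpy as np
import pytest

from gbmsurv.synthetic import SimConfig, default_coupling_matrices, generate_cohort


def dcor_oracle(X, Y):
    """Double-loop distance correlation straight from the defining sums.

    Deliberately naive (O(T^2) python loops) so it is independent of the
    vectorized implementation it checks.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    T = X.shape[0]
    a = np.zeros((T, T))
    b = np.zeros((T, T))
    for j in range(T):
        for k in range(T):
            a[j, k] = np.sqrt(np.sum((X[j] - X[k]) ** 2))
            b[j, k] = np.sqrt(np.sum((Y[j] - Y[k]) ** 2))
    A = np.zeros((T, T))
    B = np.zeros((T, T))
    for j in range(T):
        for k in range(T):
            A[j, k] = a[j, k] - a[j].mean() - a[:, k].mean() + a.mean()
            B[j, k] = b[j, k] - b[j].mean() - b[:, k].mean() + b.mean()
    dcov2 = (A * B).sum() / T**2
    dvarx = (A * A).sum() / T**2
    dvary = (B * B).sum() / T**2
    if dvarx * dvary <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))


@pytest.fixture(scope="session")
def small_sim_config():
    """A fast cohort: 5 networks, few voxels/frames, planted pair (0, 2)."""
    return SimConfig(
        n_subjects=24,
        n_networks=5,
        voxels_per_network=12,
        n_frames=60,
        coupling_matrices=default_coupling_matrices(
            5, planted_pairs=((0, 2),), coupling_by_group=(0.8, 0.5, 0.2)
        ),
        noise_sd=0.6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    return generate_cohort(small_sim_config)
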