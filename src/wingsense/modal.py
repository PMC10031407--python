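"""Proper orthogonal decomposition (POD) of spatio-temporal strain.

The analysis-wingbeat strain matrix Z (nodes x time) is factored by a
singular value decomposition Z = U S V^T: columns of U are orthonormal
spatial strain modes, columns of V the corresponding unit-norm temporal
courses, and the normalised squared singular values form the eigenvalue
(energy) spectrum.  Truncating to the leading k modes gives the best rank-k
approximation of the strain field, which feeds the encoding pipeline to
measure how detection accuracy depends on the number of modes retained.

By default the temporal mean of each node is kept in the matrix (the
spiking encoder responds to absolute strain, not fluctuations); mean
removal is available as a switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoding import EncodingParams, encode_strain_field
from .placement import SSPOCParams
from .evaluation import run_iteration
from .wing_model import StrainField

__all__ = ["ModalDecomposition", "pod_decompose", "reconstruct_k",
           "project_strain_field", "accuracy_vs_modes"]


@dataclass
class ModalDecomposition:
    """SVD factors of one condition's analysis-wingbeat strain."""

    spatial_modes: np.ndarray    # (n_nodes, r), orthonormal columns
    temporal_modes: np.ndarray   # (n_times, r), orthonormal columns
    singular_values: np.ndarray  # (r,), non-increasing
    eigenvalues: np.ndarray      # (r,), squared singular values, sum 1
    mean: np.ndarray | None      # per-node temporal mean if removed, else None

    @property
    def n_modes(self) -> int:
        return self.singular_values.size


def pod_decompose(strain: StrainField, center: bool = False) -> ModalDecomposition:
    """Decompose the analysis wingbeat into spatial/temporal strain modes.

    ``center`` subtracts each node's temporal mean before the SVD.  Mode
    signs follow a deterministic convention: the largest-magnitude entry of
    each spatial mode is positive.  An all-zero field yields an empty
    decomposition with a warning.
    """
    Z = strain.window.copy()
    mean = None
    if center:
        mean = Z.mean(axis=1, keepdims=True)
        Z = Z - mean
    if not np.any(Z):
        warnings.warn("strain field is identically zero; empty decomposition")
        return ModalDecomposition(
            spatial_modes=np.zeros((Z.shape[0], 0)),
            temporal_modes=np.zeros((Z.shape[1], 0)),
            singular_values=np.zeros(0), eigenvalues=np.zeros(0),
            mean=mean)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    keep = s > s[0] * 1e-14
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    lam = s**2 / np.sum(s**2)
    return ModalDecomposition(spatial_modes=U, temporal_modes=Vt.T,
                              singular_values=s, eigenvalues=lam, mean=mean)


def reconstruct_k(decomp: ModalDecomposition, k: int,
                  template: StrainField | None = None) -> np.ndarray | StrainField:
    """Rank-k reconstruction of the decomposed strain window.

    Returns the (nodes x time) matrix, or a copy of ``template`` whose
    analysis window holds the reconstruction when a template field is given.
    """
    if not 1 <= k <= decomp.n_modes:
        raise ValueError(f"k={k} outside [1, {decomp.n_modes}]")
    U = decomp.spatial_modes[:, :k]
    S = decomp.singular_values[:k]
    V = decomp.temporal_modes[:, :k]
    Z = (U * S) @ V.T
    if decomp.mean is not None:
        Z = Z + decomp.mean
    if template is None:
        return Z
    out = replace_window(template, Z)
    return out


def replace_window(field: StrainField, Z: np.ndarray) -> StrainField:
    """Copy of ``field`` whose analysis-window strain is replaced by Z."""
    eps = field.epsilon_xx.copy()
    i0, i1 = field.wingbeat_window
    if Z.shape != (eps.shape[0], i1 - i0):
        raise ValueError("replacement window has wrong shape")
    eps[:, i0:i1] = Z
    return replace(field, epsilon_xx=eps)


def project_strain_field(field: StrainField, basis: np.ndarray) -> StrainField:
    """Project the whole strain record onto a spatial mode basis.

    The projection U U^T is applied to every time sample (it is a purely
    spatial operation), so the filtered-strain history before the analysis
    window stays consistent with the truncated field.
    """
    U = np.asarray(basis)
    eps = U @ (U.T @ field.epsilon_xx)
    return replace(field, epsilon_xx=eps)


def accuracy_vs_modes(flap: StrainField, rot: StrainField, k_max: int,
                      enc: EncodingParams | None = None,
                      sspoc_params: SSPOCParams | None = None,
                      seed: int = 0, n_iterations: int | None = None,
                      center: bool = False) -> pd.DataFrame:
    """Detection accuracy as a function of the number of strain modes.

    The spatial basis comes from the flap-only condition and is applied to
    both conditions, so the rotation signature is expressed in the same
    modes.  For each k = 1..k_max both fields are rank-k truncated (spatial
    projection of the full record), re-encoded and re-optimised; rows give
    mean accuracy +/- SEM over iterations.
    """
    enc = enc or EncodingParams()
    sspoc_params = sspoc_params or SSPOCParams()
    n_iter = n_iterations or sspoc_params.n_iterations
    decomp = pod_decompose(flap, center=center)
    k_max = min(k_max, decomp.n_modes)
    locations = np.column_stack([flap.X, flap.Y])

    rows = []
    ss = np.random.SeedSequence(seed)
    for k in range(1, k_max + 1):
        U = decomp.spatial_modes[:, :k]
        flap_k = project_strain_field(flap, U)
        rot_k = project_strain_field(rot, U)
        accs = []
        for it in range(n_iter):
            sf_seed, sr_seed, it_seed = [
                int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
            ]
            spikes_f = encode_strain_field(flap_k, enc, rng=sf_seed,
                                           class_label="flap")
            spikes_r = encode_strain_field(rot_k, enc, rng=sr_seed,
                                           class_label="rotation")
            _, res = run_iteration(spikes_f, spikes_r, sspoc_params,
                                   seed=it_seed, locations=locations)
            accs.append(res.accuracy)
        accs = np.asarray(accs)
        sem = accs.std(ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0
        rows.append({"k": k, "accuracy_mean": accs.mean(),
                     "accuracy_sem": sem, "n_iterations": len(accs)})
    return pd.DataFrame(rows)
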