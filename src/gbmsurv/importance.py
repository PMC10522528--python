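"""Permutation-importance attribution and its network-level projection.

A feature's importance is the drop in accuracy when its values are randomly
permuted across subjects.  Each ensemble member is scored on its own
out-of-fold test subjects (never on subjects it trained on), the permutation
is redrawn ``repeats`` times, and the drops are averaged over members and
repeats.  Age, sex and cortical-thickness features report their importance
directly.

Importance carried by the encoded FC features is traced back to the 120 raw
network-pair similarities by one of two routes.  The default ("direct")
permutes each raw pair across subjects, re-encodes the perturbed connectome,
and measures the out-of-fold accuracy drop — the permutation flows through
the trained encoder exactly as a corrupted measurement would.  The
alternative ("encoder-weights") spreads each encoded feature's importance
over raw pairs in proportion to the absolute encoder weights; it is cheaper
but diffuse, because the encoder standardizes its inputs and therefore
weights class-informative and uninformative pairs alike.  Per-pair weights
are then averaged per network (each network touches 15 of the 120 pairs)
and projected onto voxel space as a weighted sum of the per-network
probability maps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import TrainedEnsemble, _member_proba
from .connectome import ProbabilityMap
from .encoder import AutoencoderModel, encode
from .errors import SchemaError, ShapeError


@dataclass
class ImportanceReport:
    per_feature: pd.Series          # accuracy drop per classifier input
    per_fc_pair: pd.Series          # normalized weight per raw network pair
    per_network: pd.DataFrame       # columns: mean, sd
    voxel_map: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [("per_feature", k, v) for k, v in self.per_feature.items()]
        rows += [("per_fc_pair", k, v) for k, v in self.per_fc_pair.items()]
        rows += [("per_network", k, r["mean"]) for k, r in self.per_network.iterrows()]
        return pd.DataFrame(rows, columns=["section", "name", "weight"])


def permutation_importance(
    ensemble: TrainedEnsemble,
    X: pd.DataFrame,
    y: pd.Series,
    repeats: int = 100,
    rng: np.random.Generator | int | None = None,
) -> pd.Series:
    """Mean out-of-fold accuracy drop per feature.

    For each ensemble member, the baseline is its accuracy on its own outer
    test fold; each feature column of that fold is then permuted ``repeats``
    times and the mean accuracy under permutation is subtracted from the
    baseline.  The result is averaged over members.
    """
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    if tuple(X.columns) != ensemble.feature_names:
        raise ShapeError("feature columns do not match the trained ensemble")
    rng = np.random.default_rng(rng)
    cls = np.asarray(ensemble.classes)

    n_feat = len(ensemble.feature_names)
    drops = np.zeros(n_feat)
    for member in ensemble.members:
        ids = list(ensemble.fold_test_ids[member.fold_id])
        Xf = X.loc[ids].to_numpy(float)
        yf = y.loc[ids].to_numpy()
        base = np.mean(cls[np.argmax(_member_proba(member, Xf, cls), axis=1)] == yf)
        for j in range(n_feat):
            acc = 0.0
            for _ in range(repeats):
                Xp = Xf.copy()
                Xp[:, j] = Xp[rng.permutation(len(ids)), j]
                pred = cls[np.argmax(_member_proba(member, Xp, cls), axis=1)]
                acc += np.mean(pred == yf)
            drops[j] += base - acc / repeats
    drops /= len(ensemble.members)
    return pd.Series(drops, index=list(ensemble.feature_names), name="importance")


def raw_pair_importance(
    ensemble: TrainedEnsemble,
    X: pd.DataFrame,
    y: pd.Series,
    encoder_model: AutoencoderModel,
    connectomes: pd.DataFrame,
    repeats: int = 5,
    rng: np.random.Generator | int | None = None,
) -> pd.Series:
    """Permute each raw FC pair, re-encode, and measure the accuracy drop.

    The returned weights are the per-pair out-of-fold accuracy drops,
    floored at zero and normalized to sum to one over the pairs, so they are
    directly comparable with :func:`attribute_encoded_to_raw`.
    """
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    if tuple(X.columns) != ensemble.feature_names:
        raise ShapeError("feature columns do not match the trained ensemble")
    missing = [sid for sid in X.index if sid not in connectomes.index]
    if missing:
        raise SchemaError(f"subjects missing from connectome table: {missing}")
    if connectomes.shape[1] != encoder_model.input_dim:
        raise SchemaError(
            f"connectome table has {connectomes.shape[1]} columns for encoder "
            f"input dim {encoder_model.input_dim}"
        )
    rng = np.random.default_rng(rng)
    cls = np.asarray(ensemble.classes)
    fc_pos = [X.columns.get_loc(name) for name in encoder_model.feature_names]

    n_pairs = connectomes.shape[1]
    drops = np.zeros(n_pairs)
    for member in ensemble.members:
        ids = list(ensemble.fold_test_ids[member.fold_id])
        n = len(ids)
        C = connectomes.loc[ids].to_numpy(float)
        Xf = X.loc[ids].to_numpy(float)
        base_feats = Xf.copy()
        base_feats[:, fc_pos] = encode(encoder_model, C)
        base = np.mean(
            cls[np.argmax(_member_proba(member, base_feats, cls), axis=1)]
            == y.loc[ids].to_numpy()
        )
        yf = y.loc[ids].to_numpy()
        for j in range(n_pairs):
            # all repeats of this pair's permutation scored in one batch
            Cr = np.tile(C, (repeats, 1))
            for r in range(repeats):
                perm = rng.permutation(n)
                Cr[r * n: (r + 1) * n, j] = C[perm, j]
            feats = np.tile(Xf, (repeats, 1))
            feats[:, fc_pos] = encode(encoder_model, Cr)
            pred = cls[np.argmax(_member_proba(member, feats, cls), axis=1)]
            drops[j] += base - np.mean(pred == np.tile(yf, repeats))
    drops /= len(ensemble.members)
    weights = np.maximum(drops, 0.0)
    total = weights.sum()
    if total > 0:
        weights = weights / total
    return pd.Series(weights, index=connectomes.columns, name="fc_pair_weight")


def attribute_encoded_to_raw(
    encoder_model: AutoencoderModel,
    per_feature: pd.Series,
    pair_labels: Sequence[str],
) -> pd.Series:
    """Trace encoded-feature importance back to raw FC pairs.

    Each raw pair's weight is the importance-weighted sum of the absolute
    encoder weights connecting that pair to each kept code unit, normalized
    to sum to one over the pairs.
    """
    kept = encoder_model.kept_features
    if kept is None:
        kept = tuple(range(encoder_model.hidden_dim))
    names = encoder_model.feature_names
    missing = [n for n in names if n not in per_feature.index]
    if missing:
        raise SchemaError(f"per-feature importances missing encoded features: {missing}")
    if len(pair_labels) != encoder_model.input_dim:
        raise SchemaError(
            f"{len(pair_labels)} pair labels for encoder input dim {encoder_model.input_dim}"
        )
    W = np.abs(encoder_model.W_enc[list(kept), :])  # (kept, pairs)
    imp = per_feature.loc[list(names)].to_numpy(float)
    raw = imp @ W
    total = raw.sum()
    if total > 0:
        raw = raw / total
    return pd.Series(raw, index=list(pair_labels), name="fc_pair_weight")


_PAIR_RE = re.compile(r"^([A-Za-z0-9]+)x([A-Za-z0-9]+)$")


def network_average_weights(per_fc_pair: pd.Series) -> pd.DataFrame:
    """Mean and SD of each network's incident pair weights.

    A network with n-1 partners has n incident pairs (its self-pair counted
    once); with 15 networks each mean runs over 15 weights.
    """
    incident: dict[str, list[float]] = {}
    for label, w in per_fc_pair.items():
        m = _PAIR_RE.match(str(label))
        if not m:
            raise SchemaError(f"malformed pair label {label!r}")
        a, b = m.group(1), m.group(2)
        incident.setdefault(a, []).append(float(w))
        if b != a:
            incident.setdefault(b, []).append(float(w))
    networks = sorted(incident)
    expected = len(networks)
    for net, ws in incident.items():
        if len(ws) != expected:
            raise SchemaError(
                f"network {net} has {len(ws)} incident pairs, expected {expected}"
            )
    return pd.DataFrame(
        {
            "mean": [float(np.mean(incident[n])) for n in networks],
            "sd": [float(np.std(incident[n])) for n in networks],
        },
        index=pd.Index(networks, name="network"),
    )


def project_to_voxels(
    per_network: pd.DataFrame | pd.Series,
    maps: Sequence[ProbabilityMap],
) -> np.ndarray:
    """Voxelwise importance: v ↦ Σ_n w̄_n · P_n(v)."""
    weights = per_network["mean"] if isinstance(per_network, pd.DataFrame) else per_network
    grid_sizes = {len(m.values) for m in maps}
    if len(grid_sizes) != 1:
        raise ShapeError(f"probability maps on different grids: {sorted(grid_sizes)}")
    missing = [m.network for m in maps if m.network not in weights.index]
    if missing:
        raise SchemaError(f"no network weight for maps: {missing}")
    out = np.zeros(grid_sizes.pop())
    for m in maps:
        out += float(weights.loc[m.network]) * m.values
    return out


def importance_report(
    ensemble: TrainedEnsemble,
    X: pd.DataFrame,
    y: pd.Series,
    encoder_model: AutoencoderModel,
    connectomes: pd.DataFrame,
    maps: Sequence[ProbabilityMap] | None = None,
    repeats: int = 100,
    raw_repeats: int = 5,
    attribution: str = "direct",
    rng: np.random.Generator | int | None = None,
) -> ImportanceReport:
    """Run the full attribution chain.

    ``attribution="direct"`` permutes raw pairs through the encoder;
    ``attribution="encoder-weights"`` distributes encoded-feature importance
    by absolute encoder weight.
    """
    rng = np.random.default_rng(rng)
    per_feature = permutation_importance(ensemble, X, y, repeats=repeats, rng=rng)
    if attribution == "direct":
        per_pair = raw_pair_importance(
            ensemble, X, y, encoder_model, connectomes,
            repeats=raw_repeats, rng=rng,
        )
    elif attribution == "encoder-weights":
        per_pair = attribute_encoded_to_raw(
            encoder_model, per_feature, list(connectomes.columns)
        )
    else:
        raise ValueError(f"unknown attribution route {attribution!r}")
    per_network = network_average_weights(per_pair)
    voxel_map = project_to_voxels(per_network, maps) if maps is not None else None
    return ImportanceReport(
        per_feature=per_feature,
        per_fc_pair=per_pair,
        per_network=per_network,
        voxel_map=voxel_map,
    )
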