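"""Multi-channel CNN -> BiLSTM -> self-attention classifier with
biological-feature fusion.

Two integer-encoded views of each sequence (alphabetical-rank tokens and
physicochemical-group tokens) pass through separate, untied channels:
embedding -> dropout -> three convolutional layers (128/64/64 filters,
stride 1, ReLU) with max pooling -> bidirectional LSTM -> single-head
self-attention over the per-position BiLSTM outputs.  Each channel yields a
2 * lstm_hidden-dimensional BiLSTM summary vector (H1, H2; 128-dim at the
defaults) and an attention-pooled vector (A1, A2).  These are concatenated
with the z-scored biological descriptor vector B and passed through a
three-layer ReLU MLP with interleaved dropout; a sigmoid turns the output
into a score in (0, 1), thresholded at 0.5 by default.

Ablation switches disable either sequence channel, the biological features,
or the attention mechanism without code changes.  Attention scores follow
the plain form softmax(K . Q) with no sqrt(d) scaling; a config flag turns
scaling on for comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .encoders import EncodedPair, encode_pair
from .io import LABEL_MESOPHILIC, LABEL_THERMOPHILIC, ProteinRecord
from .nn import Tensor

_COMP_VOCAB = 21  # 20 residues + padding
_PHYS_VOCAB = 7   # 6 groups + padding


@dataclass
class ModelConfig:
    """Architecture, training and ablation hyperparameters."""

    embed_dim: int = 128
    conv_filters: tuple[int, int, int] = (128, 64, 64)
    kernel_size: int = 3
    pool_size: int = 2
    lstm_hidden: int = 64  # per direction; summary vectors are 2x this
    attention_dim: int = 64
    mlp_hidden: tuple[int, int, int] = (256, 128, 64)
    dropout: float = 0.3
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    patience: int = 5
    seed: int = 0
    use_comp_channel: bool = True
    use_phys_channel: bool = True
    use_biofeatures: bool = True
    use_attention: bool = True
    scaled_attention: bool = False
    biofeature_dim: int = 797
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.conv_filters = tuple(self.conv_filters)
        self.mlp_hidden = tuple(self.mlp_hidden)
        if not (self.use_comp_channel or self.use_phys_channel
                or self.use_biofeatures):
            raise ValueError(
                "at least one of the two sequence channels or the "
                "biological features must be enabled"
            )
        if len(self.conv_filters) != 3 or len(self.mlp_hidden) != 3:
            raise ValueError("conv_filters and mlp_hidden must be triples")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def compact(cls, **overrides) -> "ModelConfig":
        """A small configuration for quick experiments and tests."""
        base = dict(
            embed_dim=16, conv_filters=(32, 16, 16), lstm_hidden=16,
            attention_dim=16, mlp_hidden=(32, 16, 8), dropout=0.2,
            batch_size=64, epochs=12, patience=4,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class PredictionResult:
    """One scored record; score >= threshold means thermophilic."""

    id: str
    score: float
    label: str
    threshold: float = 0.5


def _active_channels(cfg: ModelConfig) -> list[str]:
    channels = []
    if cfg.use_comp_channel:
        channels.append("comp")
    if cfg.use_phys_channel:
        channels.append("phys")
    return channels


def init_params(cfg: ModelConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """Glorot-initialized parameter dict for the configured architecture."""
    params: dict[str, Tensor] = {}
    h = cfg.lstm_hidden
    hm_dim = 2 * h
    for ch, vocab in (("comp", _COMP_VOCAB), ("phys", _PHYS_VOCAB)):
        if ch not in _active_channels(cfg):
            continue
        params[f"{ch}.embed"] = nn.glorot(rng, (vocab, cfg.embed_dim))
        c_in = cfg.embed_dim
        for i, c_out in enumerate(cfg.conv_filters):
            params[f"{ch}.conv{i}.w"] = nn.glorot(rng, (cfg.kernel_size * c_in, c_out))
            params[f"{ch}.conv{i}.b"] = nn.zeros((c_out,))
            c_in = c_out
        for d in ("f", "b"):
            params[f"{ch}.lstm.wx_{d}"] = nn.glorot(rng, (c_in, 4 * h))
            params[f"{ch}.lstm.wh_{d}"] = nn.glorot(rng, (h, 4 * h))
            bias = np.zeros(4 * h)
            bias[h:2 * h] = 1.0  # forget-gate bias
            params[f"{ch}.lstm.b_{d}"] = Tensor(bias, requires_grad=True)
        params[f"{ch}.lstm.w4"] = nn.glorot(rng, (h, hm_dim))
        params[f"{ch}.lstm.w6"] = nn.glorot(rng, (h, hm_dim))
        if cfg.use_attention:
            for name in ("wq", "wk", "wv"):
                params[f"{ch}.attn.{name}"] = nn.glorot(rng, (hm_dim, cfg.attention_dim))
    fusion_dim = 0
    for ch in _active_channels(cfg):
        fusion_dim += hm_dim + (cfg.attention_dim if cfg.use_attention else 0)
    if cfg.use_biofeatures:
        fusion_dim += cfg.biofeature_dim
    d_in = fusion_dim
    for i, d_out in enumerate(cfg.mlp_hidden):
        params[f"mlp{i}.w"] = nn.glorot(rng, (d_in, d_out))
        params[f"mlp{i}.b"] = nn.zeros((d_out,))
        d_in = d_out
    params["out.w"] = nn.glorot(rng, (d_in, 1))
    params["out.b"] = nn.zeros((1,))
    return params


def _channel_forward(params: dict[str, Tensor], ch: str, tokens: np.ndarray,
                     mask: np.ndarray, cfg: ModelConfig,
                     rng: np.random.Generator | None, training: bool
                     ) -> tuple[Tensor, Tensor | None]:
    x = nn.embed_masked(params[f"{ch}.embed"], tokens, mask)
    x = nn.dropout(x, cfg.dropout, rng, training)
    for i in range(3):
        x = nn.conv1d_same(x, params[f"{ch}.conv{i}.w"], params[f"{ch}.conv{i}.b"],
                           cfg.kernel_size, mask)
        x, mask = nn.maxpool1d(x, cfg.pool_size, mask)
    hm, h_summary = nn.bilstm(x, mask, params, f"{ch}.lstm", cfg.lstm_hidden)
    attended = None
    if cfg.use_attention:
        attended, _ = nn.self_attention_pool(
            hm, mask, params[f"{ch}.attn.wq"], params[f"{ch}.attn.wk"],
            params[f"{ch}.attn.wv"], scaled=cfg.scaled_attention,
        )
    return h_summary, attended


def forward_batch(params: dict[str, Tensor], cfg: ModelConfig,
                  comp: np.ndarray | None, phys: np.ndarray | None,
                  lengths: np.ndarray, bio: np.ndarray | None,
                  rng: np.random.Generator | None = None,
                  training: bool = False) -> Tensor:
    """Forward pass on a batch; returns the logit tensor of shape (B,)."""
    if lengths.min() <= 0:
        raise ValueError("all-padding input: every record needs >= 1 residue")
    parts: list[Tensor] = []
    tokens = {"comp": comp, "phys": phys}
    # trim to the longest true length: trailing padding is dropped before
    # any arithmetic, so scores are exactly padding-invariant
    L = int(lengths.max())
    tokens = {k: (v[:, :L] if v is not None else None)
              for k, v in tokens.items()}
    mask = (np.arange(L)[None, :] < lengths[:, None]).astype(np.float64)
    summaries: list[Tensor] = []
    attention_outs: list[Tensor] = []
    for ch in _active_channels(cfg):
        if tokens[ch] is None:
            raise ValueError(f"channel {ch!r} enabled but its tokens are missing")
        h_summary, attended = _channel_forward(params, ch, tokens[ch], mask,
                                               cfg, rng, training)
        summaries.append(h_summary)
        if attended is not None:
            attention_outs.append(attended)
    parts.extend(summaries)
    parts.extend(attention_outs)
    if cfg.use_biofeatures:
        if bio is None:
            raise ValueError("biofeatures enabled but none were provided")
        if bio.shape[1] != cfg.biofeature_dim:
            raise ValueError(
                f"biofeature dimension {bio.shape[1]} does not match the "
                f"configured {cfg.biofeature_dim}"
            )
        parts.append(Tensor(bio))
    fused = nn.concatenate(parts, axis=-1) if len(parts) > 1 else parts[0]
    x = fused
    for i in range(3):
        x = nn.linear(x, params[f"mlp{i}.w"], params[f"mlp{i}.b"]).relu()
        x = nn.dropout(x, cfg.dropout, rng, training)
    logits = nn.linear(x, params["out.w"], params["out.b"])
    return logits.reshape(-1)


def bilstm_summaries(params: dict[str, Tensor], cfg: ModelConfig,
                     pair: EncodedPair) -> dict[str, np.ndarray]:
    """The per-channel BiLSTM summary vectors (H1, H2) for one record."""
    mask = (np.arange(len(pair.comp_tokens))[None, :]
            < np.array([pair.true_length])[:, None]).astype(np.float64)
    out = {}
    tokens = {"comp": pair.comp_tokens[None, :], "phys": pair.phys_tokens[None, :]}
    for ch in _active_channels(cfg):
        h_summary, _ = _channel_forward(params, ch, tokens[ch], mask, cfg,
                                        None, False)
        out[ch] = h_summary.data[0]
    return out


def self_attention(hm: np.ndarray, mask: np.ndarray | None = None,
                   wq: np.ndarray | None = None, wk: np.ndarray | None = None,
                   wv: np.ndarray | None = None, attention_dim: int | None = None,
                   seed: int = 0, scaled: bool = False
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Self-attention over a (T, d) or (B, T, d) sequence of vectors.

    Projections default to Glorot draws from ``seed`` when not supplied.
    Returns ``(pooled, weights)`` where ``weights[b, q]`` sums to 1 over the
    unmasked key positions.
    """
    hm = np.asarray(hm, dtype=float)
    single = hm.ndim == 2
    if single:
        hm = hm[None]
    B, T, d = hm.shape
    if mask is None:
        mask = np.ones((B, T))
    mask = np.asarray(mask, dtype=np.float64).reshape(B, T)
    if mask.sum() == 0:
        raise ValueError("attention requires at least one unmasked position")
    rng = np.random.default_rng(seed)
    da = attention_dim or d
    wq_t = Tensor(wq) if wq is not None else nn.glorot(rng, (d, da))
    wk_t = Tensor(wk) if wk is not None else nn.glorot(rng, (d, da))
    wv_t = Tensor(wv) if wv is not None else nn.glorot(rng, (d, da))
    pooled, weights = nn.self_attention_pool(Tensor(hm), mask, wq_t, wk_t,
                                             wv_t, scaled=scaled)
    if single:
        return pooled.data[0], weights[0]
    return pooled.data, weights


def forward(pair: EncodedPair, biofeatures: np.ndarray | None,
            cfg: ModelConfig, params: dict[str, Tensor] | None = None
            ) -> PredictionResult:
    """Single-record forward pass (untrained weights drawn from cfg.seed)."""
    if params is None:
        params = init_params(cfg, np.random.default_rng(cfg.seed))
    bio = None
    if cfg.use_biofeatures:
        if biofeatures is None:
            raise ValueError("cfg.use_biofeatures is set but biofeatures is None")
        bio = np.asarray(biofeatures, dtype=float).reshape(1, -1)
    logits = forward_batch(
        params, cfg, pair.comp_tokens[None, :], pair.phys_tokens[None, :],
        np.array([pair.true_length]), bio,
    )
    score = float(1.0 / (1.0 + np.exp(-logits.data[0])))
    label = LABEL_THERMOPHILIC if score >= cfg.threshold else LABEL_MESOPHILIC
    return PredictionResult(pair.id, score, label, cfg.threshold)


class ThermoNetClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style estimator around the multi-channel network.

    ``fit`` takes sequences (strings or :class:`ProteinRecord`) plus binary
    labels (1 = thermophilic); the descriptor panel is computed internally
    when ``use_biofeatures`` is on and no precomputed matrix is passed.
    Biological features are z-scored with statistics fitted on the training
    split only.  Training minimizes binary cross-entropy with Adam, keeps
    the weights of the best validation-loss epoch, and is deterministic for
    a fixed ``seed``.
    """

    def __init__(self, embed_dim=128, conv_filters=(128, 64, 64), kernel_size=3,
                 pool_size=2, lstm_hidden=64, attention_dim=64,
                 mlp_hidden=(256, 128, 64), dropout=0.3, lr=1e-3, batch_size=64,
                 epochs=50, patience=5, seed=0, use_comp_channel=True,
                 use_phys_channel=True, use_biofeatures=True, use_attention=True,
                 scaled_attention=False, threshold=0.5, validation_fraction=0.1,
                 descriptor_families=("aac", "dpc", "ctd", "qso", "paac", "apaac")):
        self.embed_dim = embed_dim
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.lstm_hidden = lstm_hidden
        self.attention_dim = attention_dim
        self.mlp_hidden = mlp_hidden
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.seed = seed
        self.use_comp_channel = use_comp_channel
        self.use_phys_channel = use_phys_channel
        self.use_biofeatures = use_biofeatures
        self.use_attention = use_attention
        self.scaled_attention = scaled_attention
        self.threshold = threshold
        self.validation_fraction = validation_fraction
        self.descriptor_families = descriptor_families

    @classmethod
    def from_config(cls, cfg: ModelConfig, **extra) -> "ThermoNetClassifier":
        kwargs = {f.name: getattr(cfg, f.name) for f in fields(cfg)
                  if f.name != "biofeature_dim"}
        kwargs.update(extra)
        return cls(**kwargs)

    # -- helpers ----------------------------------------------------------
    def _config(self, biofeature_dim: int) -> ModelConfig:
        return ModelConfig(
            embed_dim=self.embed_dim, conv_filters=tuple(self.conv_filters),
            kernel_size=self.kernel_size, pool_size=self.pool_size,
            lstm_hidden=self.lstm_hidden, attention_dim=self.attention_dim,
            mlp_hidden=tuple(self.mlp_hidden), dropout=self.dropout,
            lr=self.lr, batch_size=self.batch_size, epochs=self.epochs,
            patience=self.patience, seed=self.seed,
            use_comp_channel=self.use_comp_channel,
            use_phys_channel=self.use_phys_channel,
            use_biofeatures=self.use_biofeatures,
            use_attention=self.use_attention,
            scaled_attention=self.scaled_attention,
            biofeature_dim=biofeature_dim, threshold=self.threshold,
        )

    @staticmethod
    def _sequences(X) -> list[str]:
        seqs = []
        for x in X:
            seqs.append(x.sequence if isinstance(x, ProteinRecord) else str(x))
        return seqs

    def _featurize(self, seqs: Sequence[str]) -> np.ndarray:
        from .descriptors import ProteinFeaturizer

        feat = ProteinFeaturizer(self.descriptor_families).fit([])
        self.feature_names_ = list(feat.feature_names_)
        return feat.transform(seqs)

    def _encode(self, seqs: Sequence[str], lmax: int):
        comp = np.zeros((len(seqs), lmax), dtype=np.int64)
        phys = np.zeros((len(seqs), lmax), dtype=np.int64)
        lengths = np.zeros(len(seqs), dtype=np.int64)
        for i, s in enumerate(seqs):
            pair = encode_pair(s, lmax)
            comp[i] = pair.comp_tokens
            phys[i] = pair.phys_tokens
            lengths[i] = pair.true_length
        return comp, phys, lengths

    def _standardize(self, bio: np.ndarray) -> np.ndarray:
        return (bio - self.scaler_mean_) / self.scaler_std_

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y, biofeatures: np.ndarray | None = None,
            validation_data: tuple | None = None):
        seqs = self._sequences(X)
        y = self._coerce_labels(y)
        self.classes_ = np.array([0, 1])
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")

        if self.use_biofeatures:
            bio = (np.asarray(biofeatures, dtype=float) if biofeatures is not None
                   else self._featurize(seqs))
        else:
            bio = None
        n_bio = 0 if bio is None else bio.shape[1]
        cfg = self._config(n_bio)
        self.config_ = cfg

        rng = np.random.default_rng(cfg.seed)
        # validation split (stratified) unless supplied
        if validation_data is None:
            idx = np.arange(len(seqs))
            val_idx = []
            for cls in (0, 1):
                cls_idx = idx[y == cls]
                n_val = max(1, int(round(self.validation_fraction * len(cls_idx))))
                val_idx.extend(rng.choice(cls_idx, size=n_val, replace=False))
            val_mask = np.zeros(len(seqs), dtype=bool)
            val_mask[np.array(val_idx)] = True
            tr_seqs = [s for s, m in zip(seqs, val_mask) if not m]
            va_seqs = [s for s, m in zip(seqs, val_mask) if m]
            y_tr, y_va = y[~val_mask], y[val_mask]
            bio_tr = bio[~val_mask] if bio is not None else None
            bio_va = bio[val_mask] if bio is not None else None
        else:
            tr_seqs, y_tr, bio_tr = seqs, y, bio
            va_X, y_va = validation_data[0], self._coerce_labels(validation_data[1])
            va_seqs = self._sequences(va_X)
            bio_va = (validation_data[2] if len(validation_data) > 2
                      else (self._featurize_like(va_seqs) if self.use_biofeatures
                            else None))
        if len(np.unique(y_tr)) < 2:
            raise ValueError("training split must contain both classes")

        if bio_tr is not None:
            self.scaler_mean_ = bio_tr.mean(axis=0)
            std = bio_tr.std(axis=0)
            std[std == 0] = 1.0
            self.scaler_std_ = std
            bio_tr = self._standardize(bio_tr)
            bio_va = self._standardize(bio_va) if bio_va is not None else None
        else:
            self.scaler_mean_ = self.scaler_std_ = None

        self.lmax_ = max(len(s) for s in (*tr_seqs, *va_seqs))
        comp_tr, phys_tr, len_tr = self._encode(tr_seqs, self.lmax_)
        comp_va, phys_va, len_va = self._encode(va_seqs, self.lmax_)

        params = init_params(cfg, rng)
        opt = nn.Adam(params, lr=cfg.lr)
        train_rng = np.random.default_rng(cfg.seed + 1)
        history = {"train_loss": [], "val_loss": []}
        best_val = np.inf
        best_params = None
        stale = 0
        n = len(tr_seqs)
        for epoch in range(cfg.epochs):
            order = train_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                Lb = int(len_tr[batch].max())
                opt.zero_grad()
                logits = forward_batch(
                    params, cfg,
                    comp_tr[batch, :Lb] if cfg.use_comp_channel else None,
                    phys_tr[batch, :Lb] if cfg.use_phys_channel else None,
                    len_tr[batch],
                    bio_tr[batch] if bio_tr is not None else None,
                    rng=train_rng, training=True,
                )
                loss = nn.bce_with_logits(logits, y_tr[batch])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "lower the learning rate"
                    )
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(batch)
            val_scores = self._raw_scores(params, cfg, comp_va, phys_va,
                                          len_va, bio_va)
            eps = 1e-12
            val_loss = float(-np.mean(
                y_va * np.log(val_scores + eps)
                + (1 - y_va) * np.log(1 - val_scores + eps)
            ))
            history["train_loss"].append(epoch_loss / n)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: p.data.copy() for k, p in params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        if best_params is not None:
            for k, p in params.items():
                p.data = best_params[k]
        self.params_ = params
        self.history_ = history
        self.n_biofeatures_ = n_bio
        return self

    def _featurize_like(self, seqs: Sequence[str]) -> np.ndarray:
        from .descriptors import ProteinFeaturizer

        return ProteinFeaturizer(self.descriptor_families).fit([]).transform(seqs)

    @staticmethod
    def _coerce_labels(y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "UO":
            mapping = {LABEL_THERMOPHILIC: 1, LABEL_MESOPHILIC: 0}
            y = np.array([mapping[str(v).lower()] for v in y])
        return y.astype(int)

    def _raw_scores(self, params, cfg, comp, phys, lengths, bio) -> np.ndarray:
        scores = np.empty(len(lengths))
        bs = cfg.batch_size
        for start in range(0, len(lengths), bs):
            sl = slice(start, start + bs)
            Lb = int(lengths[sl].max())
            logits = forward_batch(
                params, cfg,
                comp[sl, :Lb] if cfg.use_comp_channel else None,
                phys[sl, :Lb] if cfg.use_phys_channel else None,
                lengths[sl],
                bio[sl] if bio is not None else None,
            )
            scores[sl] = 1.0 / (1.0 + np.exp(-logits.data))
        return scores

    def predict_proba(self, X, biofeatures: np.ndarray | None = None) -> np.ndarray:
        self._check_fitted()
        seqs = self._sequences(X)
        bio = None
        if self.config_.use_biofeatures:
            bio = (np.asarray(biofeatures, dtype=float) if biofeatures is not None
                   else self._featurize_like(seqs))
            bio = self._standardize(bio)
        lmax = max(max(len(s) for s in seqs), 1)
        comp, phys, lengths = self._encode(seqs, lmax)
        p = self._raw_scores(self.params_, self.config_, comp, phys, lengths, bio)
        return np.column_stack([1 - p, p])

    def decision_function(self, X, biofeatures=None) -> np.ndarray:
        return self.predict_proba(X, biofeatures)[:, 1]

    def predict(self, X, biofeatures=None) -> np.ndarray:
        p = self.predict_proba(X, biofeatures)[:, 1]
        return (p >= self.threshold).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("classifier is not fitted; call fit() first")

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a single-archive checkpoint (weights, config, scaler)."""
        self._check_fitted()
        arrays = {f"param:{k}": p.data for k, p in self.params_.items()}
        meta = {
            "config": asdict(self.config_),
            "params": self.get_params(),
            "feature_names": getattr(self, "feature_names_", None),
            "n_biofeatures": self.n_biofeatures_,
            "lmax": self.lmax_,
            "history": self.history_,
        }
        if self.scaler_mean_ is not None:
            arrays["scaler_mean"] = self.scaler_mean_
            arrays["scaler_std"] = self.scaler_std_
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ThermoNetClassifier":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            est_params = meta["params"]
            est_params["conv_filters"] = tuple(est_params["conv_filters"])
            est_params["mlp_hidden"] = tuple(est_params["mlp_hidden"])
            est_params["descriptor_families"] = tuple(
                est_params["descriptor_families"])
            clf = cls(**est_params)
            cfg_dict = meta["config"]
            cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
            cfg_dict["mlp_hidden"] = tuple(cfg_dict["mlp_hidden"])
            clf.config_ = ModelConfig(**cfg_dict)
            clf.params_ = {
                k[len("param:"):]: Tensor(archive[k], requires_grad=True)
                for k in archive.files if k.startswith("param:")
            }
            clf.scaler_mean_ = (archive["scaler_mean"]
                                if "scaler_mean" in archive.files else None)
            clf.scaler_std_ = (archive["scaler_std"]
                               if "scaler_std" in archive.files else None)
            clf.n_biofeatures_ = meta["n_biofeatures"]
            clf.lmax_ = meta["lmax"]
            clf.history_ = meta["history"]
            if meta["feature_names"] is not None:
                clf.feature_names_ = meta["feature_names"]
            clf.classes_ = np.array([0, 1])
        return clf


def train(train_set, val_set, cfg: ModelConfig):
    """Train on explicit (EncodedPair, FeatureVector, label) triples.

    Thin functional wrapper over :class:`ThermoNetClassifier` for callers
    that already hold encoded pairs; returns ``(classifier, history)``.
    """
    from .encoders import decode_composition

    def unpack(dataset):
        seqs, bios, labels = [], [], []
        for pair, fv, label in dataset:
            seqs.append(decode_composition(pair.comp_tokens))
            bios.append(None if fv is None else np.asarray(fv.values, dtype=float))
            labels.append(label)
        bio = None if bios[0] is None else np.vstack(bios)
        return seqs, bio, np.asarray(labels)

    tr_seqs, tr_bio, y_tr = unpack(train_set)
    va_seqs, va_bio, y_va = unpack(val_set)
    clf = ThermoNetClassifier.from_config(cfg)
    clf.fit(tr_seqs, y_tr, biofeatures=tr_bio,
            validation_data=(va_seqs, y_va, va_bio))
    return clf, clf.history_


def predict_batch(records: Iterable[ProteinRecord], checkpoint: str | Path
                  ) -> tuple[list[PredictionResult], list[tuple[str, str]]]:
    """Score records with a saved checkpoint; per-record failures are
    reported (id, message) and the batch continues."""
    clf = ThermoNetClassifier.load(checkpoint)
    results: list[PredictionResult] = []
    errors: list[tuple[str, str]] = []
    for rec in records:
        try:
            bio = None
            if clf.config_.use_biofeatures:
                from .descriptors import featurize

                bio = featurize(rec, clf.descriptor_families).values[None, :]
            p = clf.predict_proba([rec.sequence], biofeatures=bio)[0, 1]
            label = (LABEL_THERMOPHILIC if p >= clf.threshold
                     else LABEL_MESOPHILIC)
            results.append(PredictionResult(rec.id, float(p), label,
                                            clf.threshold))
        except (ValueError, RuntimeError) as exc:
            errors.append((rec.id, str(exc)))
    return results, errors
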