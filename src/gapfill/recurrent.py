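"""Recurrent gap imputers: the BiLSTM-I encoder-decoder and a BRITS-I baseline.

**BiLSTM-I.** One sequence step is one day: a 48-vector of half-hourly
temperatures. Each encoder direction is an *LSTM-I* cell: before the LSTM
update, the previous hidden state is projected to an estimate
``x̃_t = W_x·h_{t−1} + b_x`` and substituted into the input at masked
positions, ``x_tᶜ = x_t⊙m_t + (1−m_t)⊙x̃_t``. The forward and backward
hidden sequences are concatenated and fed step-by-step to an LSTM decoder
topped by an affine layer producing the imputed day ``y_t``. The training
objective has three parts: the forward and backward encoder estimation
errors and the decoder imputation error, each a masked mean absolute error
scored only at artificially hidden positions (training windows are cut from
fully observed stretches, so the hidden truth is known).

**BRITS-I baseline.** Two unidirectional RITS-I recurrences (forward and
backward) with a temporal-decay factor ``γ_t = exp(−max(0, W_γ·δ_t + b_γ))``
applied to the hidden state, where δ_t counts steps since each slot was last
observed. The final estimate is the mean of the two directional estimates,
and the loss adds a forward/backward consistency term.

All gradients flow through :mod:`gapfill.autodiff`; training uses Adam with
early stopping on a held-out window split. Observed values are never
modified by imputation — filled outputs are bit-identical to the input at
observed positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Adam, Var, concat
from .series import WindowSample

__all__ = [
    "TrainConfig", "LstmIParams", "DecoderParams", "DecayParams",
    "RnnBaselineParams", "TrainedImputer", "LossReport",
    "lstm_i_step", "encode_bidirectional", "decode", "loss_total",
    "temporal_decay", "train_bilstm_i", "impute_window",
    "train_brits_i", "impute_brits_i",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults: Adam 1e-3, batch 16, ≤200 epochs,
    early stopping with patience 20 on a held-out window split)."""

    hidden: int = 64
    dec_hidden: int = 64
    lr: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 200
    patience: int = 20
    val_frac: float = 0.1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LstmIParams:
    """One encoder direction: estimate head (W_x, b_x) + LSTM gate block."""

    W_x: Var       # (h, slots)
    b_x: Var       # (slots,)
    W: Var         # (slots + h, 4h) gates ordered [i, f, g, o]
    b: Var         # (4h,)
    direction: str = "forward"


@dataclass
class DecoderParams:
    W: Var         # (2h + h_dec, 4h_dec)
    b: Var         # (4h_dec,)
    W_y: Var       # (h_dec, slots)
    b_y: Var       # (slots,)


@dataclass
class DecayParams:
    W_gamma: Var   # (slots, h)
    b_gamma: Var   # (h,)


@dataclass
class RnnBaselineParams:
    """Plain sigmoid recurrence h_t = σ(W_h h_{t−1} + U_h x_t + b_h)."""

    W_h: Var
    U_h: Var
    b_h: Var

    def step(self, x: Var, h: Var) -> Var:
        return (h @ self.W_h + x @ self.U_h + self.b_h).sigmoid()


@dataclass
class LossReport:
    l_f: float
    l_b: float
    l_y: float

    @property
    def total(self) -> float:
        return self.l_f + self.l_b + self.l_y


@dataclass
class TrainedImputer:
    """Serialized model: architecture tag, parameters, normalization, config."""

    arch: str                       # "bilstm_i" | "brits_i"
    params: dict                    # name -> ndarray
    norm_mean: float
    norm_sd: float
    config: dict
    seed: int
    n_slots: int = 48
    log: list = field(default_factory=list)

    def __post_init__(self):
        if not self.norm_sd > 0:
            raise ValueError("normalization sd must be > 0")

    def to_json(self) -> str:
        d = {"arch": self.arch, "norm_mean": self.norm_mean,
             "norm_sd": self.norm_sd, "config": self.config, "seed": self.seed,
             "n_slots": self.n_slots, "log": self.log,
             "params": {k: v.tolist() for k, v in self.params.items()}}
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TrainedImputer":
        d = json.loads(text)
        d["params"] = {k: np.asarray(v, dtype=float) for k, v in d["params"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _init_lstm(rng, n_in: int, n_hidden: int) -> tuple[Var, Var]:
    k = 1.0 / np.sqrt(n_hidden)
    W = Var(rng.uniform(-k, k, size=(n_in + n_hidden, 4 * n_hidden)))
    b0 = rng.uniform(-k, k, size=4 * n_hidden)
    b0[n_hidden:2 * n_hidden] += 1.0  # forget-gate bias: remember by default
    return W, Var(b0)


def _init_affine(rng, n_in: int, n_out: int) -> tuple[Var, Var]:
    k = 1.0 / np.sqrt(n_in)
    return Var(rng.uniform(-k, k, size=(n_in, n_out))), \
        Var(rng.uniform(-k, k, size=n_out))


def _init_bilstm(rng, slots: int, cfg: TrainConfig) -> dict[str, Var]:
    p = {}
    for d in ("f", "b"):
        p[f"enc_{d}_Wx"], p[f"enc_{d}_bx"] = _init_affine(rng, cfg.hidden, slots)
        p[f"enc_{d}_W"], p[f"enc_{d}_b"] = _init_lstm(rng, slots, cfg.hidden)
    p["dec_W"], p["dec_b"] = _init_lstm(rng, 2 * cfg.hidden, cfg.dec_hidden)
    p["dec_Wy"], p["dec_by"] = _init_affine(rng, cfg.dec_hidden, slots)
    return p


def _init_brits(rng, slots: int, cfg: TrainConfig) -> dict[str, Var]:
    p = {}
    for d in ("f", "b"):
        p[f"{d}_Wx"], p[f"{d}_bx"] = _init_affine(rng, cfg.hidden, slots)
        p[f"{d}_W"], p[f"{d}_b"] = _init_lstm(rng, slots, cfg.hidden)
        p[f"{d}_Wg"], p[f"{d}_bg"] = _init_affine(rng, slots, cfg.hidden)
    return p


def _enc_params(p: dict, d: str) -> LstmIParams:
    return LstmIParams(W_x=p[f"enc_{d}_Wx"], b_x=p[f"enc_{d}_bx"],
                       W=p[f"enc_{d}_W"], b=p[f"enc_{d}_b"],
                       direction="forward" if d == "f" else "backward")


def _dec_params(p: dict) -> DecoderParams:
    return DecoderParams(W=p["dec_W"], b=p["dec_b"], W_y=p["dec_Wy"], b_y=p["dec_by"])


# ---------------------------------------------------------------------------
# forward building blocks
# ---------------------------------------------------------------------------

def _lstm_cell(x: Var, h: Var, c: Var, W: Var, b: Var) -> tuple[Var, Var]:
    nh = h.shape[1]
    z = concat([x, h], axis=1) @ W + b
    i = z[:, 0 * nh:1 * nh].sigmoid()
    f = z[:, 1 * nh:2 * nh].sigmoid()
    g = z[:, 2 * nh:3 * nh].tanh()
    o = z[:, 3 * nh:4 * nh].sigmoid()
    c_new = f * c + i * g
    h_new = o * c_new.tanh()
    return h_new, c_new


def lstm_i_step(x_t: np.ndarray, m_t: np.ndarray, h_prev: Var, c_prev: Var,
                params: LstmIParams, truth_t: np.ndarray | None = None,
                loss_mask_t: np.ndarray | None = None
                ) -> tuple[Var, Var, Var, Var | float]:
    """One LSTM-I step: estimate, substitute at masked slots, LSTM update.

    ``x_t``/``m_t`` are (batch, slots) arrays (NaN allowed where m == 0).
    Returns (h_t, c_t, x̃_t, loss_contrib) where loss_contrib is the summed
    masked absolute error |truth − x̃| (0 when no truth given).
    """
    m = m_t.astype(float)
    x_tilde = h_prev @ params.W_x + params.b_x
    x_obs = np.nan_to_num(np.where(m > 0, x_t, 0.0))
    x_c = Var(x_obs) + (1.0 - m) * x_tilde
    h_t, c_t = _lstm_cell(x_c, h_prev, c_prev, params.W, params.b)
    loss_contrib: Var | float = 0.0
    if truth_t is not None and loss_mask_t is not None and loss_mask_t.any():
        lm = loss_mask_t.astype(float)
        if np.isnan(truth_t[loss_mask_t.astype(bool)]).any():
            raise ValueError("truth missing at a loss-scored position")
        diff = (x_tilde - np.nan_to_num(truth_t)) * lm
        loss_contrib = diff.abs().sum()
    return h_t, c_t, x_tilde, loss_contrib


def _run_direction(values, mask, params: LstmIParams, truth=None, loss_mask=None):
    """Run one encoder direction over (B, w, slots) arrays.

    Returns hidden states and estimates aligned to the *original* day order,
    plus the accumulated loss sum.
    """
    B, w, slots = values.shape
    nh = params.W.shape[1] // 4
    order = range(w) if params.direction == "forward" else range(w - 1, -1, -1)
    h = Var(np.zeros((B, nh)))
    c = Var(np.zeros((B, nh)))
    hs: list[Var | None] = [None] * w
    xt: list[Var | None] = [None] * w
    loss_sum: Var | float = 0.0
    for t in order:
        tt = truth[:, t] if truth is not None else None
        lmt = loss_mask[:, t] if loss_mask is not None else None
        h, c, x_tilde, lc = lstm_i_step(values[:, t], mask[:, t], h, c, params, tt, lmt)
        hs[t] = h
        xt[t] = x_tilde
        if not isinstance(lc, float):
            loss_sum = loss_sum + lc if not isinstance(loss_sum, float) else lc
    return hs, xt, loss_sum


def encode_bidirectional(values, mask, fwd: LstmIParams, bwd: LstmIParams,
                         truth=None, loss_mask=None):
    """Bidirectional LSTM-I pass; h_t = [h→_t, h←_t] in original order.

    Returns (hs, x̃_f, x̃_b, l_f_sum, l_b_sum) with hs a length-w list of
    (B, 2h) Vars.
    """
    hf, xf, lf = _run_direction(values, mask, fwd, truth, loss_mask)
    hb, xb, lb = _run_direction(values, mask, bwd, truth, loss_mask)
    hs = [concat([hf[t], hb[t]], axis=1) for t in range(len(hf))]
    return hs, xf, xb, lf, lb


def decode(hs: list[Var], params: DecoderParams) -> list[Var]:
    """LSTM decoder over the encoded sequence + affine output head."""
    B = hs[0].shape[0]
    nh = params.W.shape[1] // 4
    s = Var(np.zeros((B, nh)))
    c = Var(np.zeros((B, nh)))
    ys = []
    for h_t in hs:
        s, c = _lstm_cell(h_t, s, c, params.W, params.b)
        ys.append(s @ params.W_y + params.b_y)
    return ys


def loss_total(sample: WindowSample, x_tilde_f: np.ndarray, x_tilde_b: np.ndarray,
               y: np.ndarray) -> LossReport:
    """Three-part objective on one window: l_f + l_b + l_y, each the mean
    absolute error over the artificially hidden (loss-masked) positions."""
    lm = sample.loss_mask.astype(bool)
    n = lm.sum()
    if n == 0:
        raise ValueError("empty loss mask: nothing to score")
    truth = sample.target_values
    if np.isnan(truth[lm]).any():
        raise ValueError("truth missing at a loss-scored position")
    l_f = float(np.abs(truth[lm] - x_tilde_f[lm]).mean())
    l_b = float(np.abs(truth[lm] - x_tilde_b[lm]).mean())
    l_y = float(np.abs(truth[lm] - y[lm]).mean())
    return LossReport(l_f=l_f, l_b=l_b, l_y=l_y)


def temporal_decay(delta: np.ndarray, params: DecayParams) -> Var:
    """γ_t = exp(−max(0, W_γ·δ_t + b_γ)); always in (0, 1]."""
    pre = Var(np.asarray(delta, dtype=float)) @ params.W_gamma + params.b_gamma
    return (-(pre.relu())).exp()


def compute_lags(mask: np.ndarray, direction: str = "forward") -> np.ndarray:
    """δ_t per slot: steps since that slot was last observed (BRITS style)."""
    B, w, slots = mask.shape
    m = mask if direction == "forward" else mask[:, ::-1]
    delta = np.zeros((B, w, slots))
    for t in range(1, w):
        delta[:, t] = np.where(m[:, t - 1] > 0, 1.0, delta[:, t - 1] + 1.0)
    return delta if direction == "forward" else delta[:, ::-1]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _stack(samples: list[WindowSample]):
    shapes = {s.input_values.shape for s in samples}
    if len(shapes) != 1:
        raise ValueError(f"samples have mixed shapes: {shapes}")
    X = np.stack([s.input_values for s in samples])
    M = np.stack([s.input_mask for s in samples]).astype(float)
    T = np.stack([s.target_values for s in samples])
    LM = np.stack([s.loss_mask for s in samples]).astype(float)
    return X, M, T, LM


def _bilstm_forward_loss(p: dict, X, M, T, LM):
    """Scalar Var objective (l_f + l_b + l_y, each mean over scored entries)."""
    n_scored = max(LM.sum(), 1.0)
    hs, xf, xb, lf, lb = encode_bidirectional(X, M, _enc_params(p, "f"),
                                              _enc_params(p, "b"), T, LM)
    ys = decode(hs, _dec_params(p))
    ly: Var | float = 0.0
    for t, y_t in enumerate(ys):
        lm_t = LM[:, t]
        if lm_t.any():
            diff = (y_t - np.nan_to_num(T[:, t])) * lm_t
            contrib = diff.abs().sum()
            ly = ly + contrib if not isinstance(ly, float) else contrib
    scale = 1.0 / n_scored
    total = (lf + lb + ly) * scale
    parts = (float(lf.value) * scale if not isinstance(lf, float) else 0.0,
             float(lb.value) * scale if not isinstance(lb, float) else 0.0,
             float(ly.value) * scale if not isinstance(ly, float) else 0.0)
    return total, parts


def _brits_forward(p: dict, X, M, T=None, LM=None, want_loss=True):
    """RITS-I in both directions; returns per-direction estimates and losses."""
    B, w, slots = X.shape
    ests = {}
    losses = {}
    for d in ("f", "b"):
        direction = "forward" if d == "f" else "backward"
        delta = compute_lags(M, direction)
        nh = p[f"{d}_W"].shape[1] // 4
        order = range(w) if d == "f" else range(w - 1, -1, -1)
        h = Var(np.zeros((B, nh)))
        c = Var(np.zeros((B, nh)))
        est: list[Var | None] = [None] * w
        loss_sum: Var | float = 0.0
        for t in order:
            gamma = temporal_decay(delta[:, t], DecayParams(p[f"{d}_Wg"], p[f"{d}_bg"]))
            h = h * gamma
            x_hat = h @ p[f"{d}_Wx"] + p[f"{d}_bx"]
            est[t] = x_hat
            m = M[:, t]
            x_obs = np.nan_to_num(np.where(m > 0, X[:, t], 0.0))
            x_c = Var(x_obs) + (1.0 - m) * x_hat
            h, c = _lstm_cell(x_c, h, c, p[f"{d}_W"], p[f"{d}_b"])
            if want_loss and LM is not None and LM[:, t].any():
                diff = (x_hat - np.nan_to_num(T[:, t])) * LM[:, t]
                lc = diff.abs().sum()
                loss_sum = loss_sum + lc if not isinstance(loss_sum, float) else lc
        ests[d] = est
        losses[d] = loss_sum
    return ests, losses


def _brits_forward_loss(p: dict, X, M, T, LM):
    n_scored = max(LM.sum(), 1.0)
    ests, losses = _brits_forward(p, X, M, T, LM, want_loss=True)
    w = X.shape[1]
    cons: Var | float = 0.0
    for t in range(w):
        d = (ests["f"][t] - ests["b"][t]).abs().sum()
        cons = cons + d if not isinstance(cons, float) else d
    n_all = X.size
    total = (losses["f"] + losses["b"]) * (1.0 / n_scored) + cons * (1.0 / n_all)
    parts = (float(losses["f"].value) / n_scored if not isinstance(losses["f"], float) else 0.0,
             float(losses["b"].value) / n_scored if not isinstance(losses["b"], float) else 0.0,
             float(cons.value) / n_all)
    return total, parts


def _train(arch: str, samples: list[WindowSample], config: TrainConfig | None,
           seed: int) -> TrainedImputer:
    cfg = config or TrainConfig()
    if not samples:
        raise ValueError("need at least one training sample")
    rng = np.random.default_rng(seed)
    X, M, T, LM = _stack(samples)
    slots = X.shape[2]

    norm_mean = float(np.nanmean(T))
    norm_sd = float(np.nanstd(T))
    if norm_sd == 0:
        norm_sd = 1.0
    Xn = (X - norm_mean) / norm_sd
    Tn = (T - norm_mean) / norm_sd

    n = len(samples)
    idx = rng.permutation(n)
    n_val = int(round(cfg.val_frac * n))
    n_val = min(n_val, n - 1)
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    if n_val == 0:
        val_idx = tr_idx  # tiny runs: validate on the training windows

    p = _init_bilstm(rng, slots, cfg) if arch == "bilstm_i" else _init_brits(rng, slots, cfg)
    forward_loss = _bilstm_forward_loss if arch == "bilstm_i" else _brits_forward_loss
    names = sorted(p)
    opt = Adam([p[k] for k in names], lr=cfg.lr)

    best_val = np.inf
    best_params = {k: p[k].value.copy() for k in names}
    best_epoch = 0
    log = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(tr_idx)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, order.size, cfg.batch_size):
            b = order[start:start + cfg.batch_size]
            total, _ = forward_loss(p, Xn[b], M[b], Tn[b], LM[b])
            if not np.isfinite(total.value):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; diverged")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_loss += float(total.value)
            n_batches += 1
        val_total, parts = forward_loss(p, Xn[val_idx], M[val_idx], Tn[val_idx], LM[val_idx])
        val = float(val_total.value)
        log.append({"epoch": epoch, "train_loss": ep_loss / max(n_batches, 1),
                    "val_loss": val, "l_f": parts[0], "l_b": parts[1],
                    "l_y": parts[2]})
        if val < best_val - 1e-6:
            best_val = val
            best_epoch = epoch
            best_params = {k: p[k].value.copy() for k in names}
        elif epoch - best_epoch >= cfg.patience:
            break
    return TrainedImputer(arch=arch, params=best_params, norm_mean=norm_mean,
                          norm_sd=norm_sd, config=cfg.to_dict(), seed=seed,
                          n_slots=slots, log=log)


def train_bilstm_i(samples: list[WindowSample], config: TrainConfig | None = None,
                   seed: int = 0) -> TrainedImputer:
    """Train the BiLSTM-I encoder-decoder on masked rolling windows."""
    return _train("bilstm_i", samples, config, seed)


def train_brits_i(samples: list[WindowSample], config: TrainConfig | None = None,
                  seed: int = 0) -> TrainedImputer:
    """Train the BRITS-I-style bidirectional recurrent baseline."""
    return _train("brits_i", samples, config, seed)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _params_as_vars(model: TrainedImputer) -> dict[str, Var]:
    return {k: Var(v) for k, v in model.params.items()}


def impute_window(model: TrainedImputer, window: WindowSample
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Fill one window; returns (values °C, provenance) where provenance is
    True at imputed positions. Observed positions are returned unchanged."""
    if window.input_values.shape[1] != model.n_slots:
        raise ValueError(f"window has {window.input_values.shape[1]} slots, "
                         f"model expects {model.n_slots}")
    X = window.input_values[None]
    M = window.input_mask[None].astype(float)
    Xn = (X - model.norm_mean) / model.norm_sd
    p = _params_as_vars(model)
    if model.arch == "bilstm_i":
        hs, *_ = encode_bidirectional(Xn, M, _enc_params(p, "f"), _enc_params(p, "b"))
        ys = decode(hs, _dec_params(p))
        est = np.stack([y.value[0] for y in ys])
    elif model.arch == "brits_i":
        ests, _ = _brits_forward(p, Xn, M, want_loss=False)
        est = np.stack([0.5 * (ests["f"][t].value[0] + ests["b"][t].value[0])
                        for t in range(X.shape[1])])
    else:
        raise ValueError(f"unknown architecture {model.arch!r}")
    est = est * model.norm_sd + model.norm_mean
    observed = window.input_mask.astype(bool)
    filled = np.where(observed, window.input_values, est)
    return filled, ~observed


def impute_brits_i(model: TrainedImputer, window: WindowSample):
    """Alias of :func:`impute_window` for the BRITS-I architecture."""
    if model.arch != "brits_i":
        raise ValueError("model is not a BRITS-I imputer")
    return impute_window(model, window)
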