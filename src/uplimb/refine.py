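"""The sequence-to-sequence refinement network and its cross-validation
harness.

A stacked 3-layer LSTM (100 units per layer) maps the 101-step, 4-channel
depth-sensor angle sequence to the gold-standard sequence; a time-distributed
linear head projects the top hidden state to the 4 output channels at every
step. Input and target are min-max scaled to [0,1] with one shared per-channel
map fitted on the training folds. Training minimizes mean squared error with
Adam (defaults: batch 20, learning rate 0.006, 200 epochs), whole sequences
as samples, no early stopping, incomplete final batch kept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import _lstm
from .datamodel import AngleWaveform, CHANNELS, ValidationError
from .evaluate import cmc, rmse
from .pipeline import prepare_pair
from .preprocess import ChannelScaler

SEQ_LEN = 101
N_CHANNELS = len(CHANNELS)


class DivergenceError(RuntimeError):
    """Training loss became NaN; try a smaller learning rate."""


class LSTMRefiner(BaseEstimator, RegressorMixin):
    """Sequence-to-sequence LSTM regressor on (n, 101, 4) arrays in [0,1].

    Parameters
    ----------
    hidden_size : int, default 100
    n_layers : int, default 3
    epochs : int, default 200
    batch_size : int, default 20
    learning_rate : float, default 0.006
        Adam step size.
    random_state : int, default 0
        Seeds weight initialization and epoch shuffling; training is
        bit-reproducible for a fixed seed.
    shuffle : bool, default True
        Reshuffle sample order each epoch.
    warmup : int, default 8
        Number of edge-padded warm-up steps prepended to every sequence so
        the recurrent state settles before the first real sample; the
        corresponding outputs are discarded. Without it the zero initial
        state leaves a short spurious transient at the sequence start that
        inflates range-of-motion estimates.

    Attributes
    ----------
    params_ : list of dict
        LSTM layer weights plus the linear output head.
    loss_history_ : list of float
        Mean training MSE per epoch (unit-interval scale).
    final_loss_ : float
    """

    def __init__(self, hidden_size=100, n_layers=3, epochs=200, batch_size=20,
                 learning_rate=0.006, random_state=0, shuffle=True, warmup=8):
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.shuffle = shuffle
        self.warmup = warmup

    def _pad(self, X):
        if not self.warmup:
            return X
        head = np.repeat(X[:, :1], self.warmup, axis=1)
        return np.concatenate([head, X], axis=1)

    def _validate(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != SEQ_LEN or X.shape[2] != N_CHANNELS:
            raise ValidationError(
                f"X must be (n, {SEQ_LEN}, {N_CHANNELS}), got {X.shape}")
        if y is not None:
            y = np.asarray(y, dtype=np.float32)
            if y.shape != X.shape:
                raise ValidationError(f"y shape {y.shape} != X shape {X.shape}")
            return X, y
        return X

    def fit(self, X, y):
        X, y = self._validate(X, y)
        if len(X) < 2:
            raise ValidationError("need at least 2 training pairs")
        rng = np.random.default_rng(self.random_state)
        self.params_ = _lstm.init_lstm_params(
            N_CHANNELS, self.hidden_size, self.n_layers, N_CHANNELS, rng)
        opt = _lstm.Adam(self.params_, lr=self.learning_rate)
        X = self._pad(X)
        y = self._pad(y)
        n = len(X)
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                Y, caches = _lstm.forward(self.params_, X[idx])
                loss, dY = _lstm.mse_loss_and_grad(Y, y[idx])
                if not np.isfinite(loss):
                    raise DivergenceError(
                        "NaN training loss; reduce the learning rate")
                grads = _lstm.backward(self.params_, caches, dY)
                opt.step(self.params_, grads)
                epoch_loss += loss * len(idx)
            self.loss_history_.append(epoch_loss / n)
        self.final_loss_ = self.loss_history_[-1]
        self._warn_if_not_converging()
        self.n_features_in_ = N_CHANNELS
        return self

    def _warn_if_not_converging(self, window=20):
        h = np.asarray(self.loss_history_)
        if len(h) < 2 * window:
            return
        if h[-window:].mean() > h[:window].mean():
            warnings.warn("training loss did not decrease in moving average",
                          RuntimeWarning)

    def predict(self, X):
        X = self._validate(X)
        if not hasattr(self, "params_"):
            raise ValidationError("model is not fitted")
        Y, _ = _lstm.forward(self.params_, self._pad(X), want_cache=False)
        if self.warmup:
            Y = Y[:, self.warmup:]
        return Y.astype(np.float64)


@dataclass
class RefineModel:
    """A trained refiner bundled with its scaler and training metadata."""

    net: LSTMRefiner
    scaler: ChannelScaler
    task: str = None
    metadata: dict = field(default_factory=dict)

    def save(self, path):
        """Serialize weights + scaler + metadata to one .npz archive."""
        arrays = {}
        for li, layer in enumerate(self.net.params_):
            for k, v in layer.items():
                arrays[f"layer{li}_{k}"] = v
        arrays["scaler_min"] = self.scaler.data_min_
        arrays["scaler_max"] = self.scaler.data_max_
        meta = dict(self.metadata)
        meta["task"] = self.task
        meta["estimator_params"] = self.net.get_params()
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        return str(path)

    @classmethod
    def load(cls, path):
        data = np.load(path)
        meta = json.loads(bytes(data["meta_json"]).decode())
        net = LSTMRefiner(**meta.pop("estimator_params"))
        layers = {}
        for key in data.files:
            if key.startswith("layer"):
                li, name = key[5:].split("_", 1)
                layers.setdefault(int(li), {})[name] = data[key]
        net.params_ = [layers[i] for i in sorted(layers)]
        net.loss_history_ = meta.get("loss_history", [])
        scaler = ChannelScaler()
        scaler.data_min_ = data["scaler_min"]
        scaler.data_max_ = data["scaler_max"]
        return cls(net=net, scaler=scaler, task=meta.pop("task", None), metadata=meta)


def train(pairs, epochs=200, batch_size=20, learning_rate=0.006, seed=0,
          task=None, scaler=None) -> RefineModel:
    """Train a refiner on (input, target) waveform pairs.

    ``pairs``: iterable of (AngleWaveform, AngleWaveform), both normalized to
    101 samples, in degrees. A shared scaler is fitted on the pooled inputs
    and targets unless one is supplied.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValidationError("need at least 2 training pairs")
    for a, b in pairs:
        if a.n_frames != SEQ_LEN or b.n_frames != SEQ_LEN:
            raise ValidationError("training waveforms must be 101-point normalized")
    if scaler is None:
        scaler = ChannelScaler().fit([w.values for pair in pairs for w in pair])
    X = scaler.transform(np.stack([a.values for a, _ in pairs]))
    Y = scaler.transform(np.stack([b.values for _, b in pairs]))
    net = LSTMRefiner(epochs=epochs, batch_size=batch_size,
                      learning_rate=learning_rate, random_state=seed)
    net.fit(X, Y)
    return RefineModel(net=net, scaler=scaler, task=task,
                       metadata={"epochs": epochs, "batch_size": batch_size,
                                 "learning_rate": learning_rate, "seed": seed,
                                 "final_loss": net.final_loss_,
                                 "n_pairs": len(pairs)})


def refine(model: RefineModel, wf: AngleWaveform) -> AngleWaveform:
    """Apply the trained network to a 101-point depth-sensor waveform."""
    if wf.n_frames != SEQ_LEN:
        raise ValidationError("refine expects a 101-point normalized waveform")
    if model.task is not None and wf.task is not None and model.task != wf.task:
        warnings.warn(f"model task {model.task!r} != waveform task {wf.task!r}")
    x = model.scaler.transform(wf.values[None])
    y = model.net.predict(x)
    values = model.scaler.inverse_transform(y)[0]
    out = wf.replace_values(values, normalized=True)
    out.meta["refined"] = True
    return out


@dataclass
class FoldResult:
    """One leave-one-subject-out fold: held-out subject and its statistics."""

    subject_id: str
    task: str
    inputs: list        # held-out depth-sensor waveforms (101x4, degrees)
    targets: list       # gold-standard counterparts
    refined: list       # network outputs
    rmse_before: np.ndarray  # (n_trials, 4)
    rmse_after: np.ndarray
    cmc_before: np.ndarray
    cmc_after: np.ndarray
    model: RefineModel = None


def loocv(corpus, task, seed=7, epochs=200, batch_size=20, learning_rate=0.006,
          keep_models=False, pair_cache=None):
    """Leave-one-subject-out cross-validation of the refiner for one task.

    ``corpus``: iterable of TrialRecords (any mix of tasks; filtered here).
    One network is trained per fold; its scaler is fitted on the training
    subjects only. Returns a list of FoldResult covering every subject once.
    """
    trials = [t for t in corpus if t.task == task]
    subjects = sorted({t.subject_id for t in trials})
    if len(subjects) < 3:
        raise ValidationError(f"need >= 3 subjects for task {task}, got {len(subjects)}")
    pairs = {}
    for tr in trials:
        key = (tr.subject_id, tr.task, tr.trial_id)
        if pair_cache is not None and key in pair_cache:
            pairs[key] = pair_cache[key]
        else:
            pairs[key] = prepare_pair(tr)
            if pair_cache is not None:
                pair_cache[key] = pairs[key]

    results = []
    for fi, held_out in enumerate(subjects):
        train_keys = [k for k in pairs if k[0] != held_out]
        test_keys = [k for k in pairs if k[0] == held_out]
        if any(k[0] == held_out for k in train_keys):
            raise RuntimeError("subject leakage in LOOCV fold construction")
        fold_seed = int(seed) * 1000 + fi
        model = train([pairs[k] for k in train_keys], epochs=epochs,
                      batch_size=batch_size, learning_rate=learning_rate,
                      seed=fold_seed, task=task)
        inputs, targets, refined = [], [], []
        rb, ra, cb, ca = [], [], [], []
        for k in test_keys:
            k_phi, k_gamma = pairs[k]
            k_hat = refine(model, k_phi)
            inputs.append(k_phi)
            targets.append(k_gamma)
            refined.append(k_hat)
            rb.append([rmse(k_phi.values[:, c], k_gamma.values[:, c])
                       for c in range(N_CHANNELS)])
            ra.append([rmse(k_hat.values[:, c], k_gamma.values[:, c])
                       for c in range(N_CHANNELS)])
            cb.append([cmc(np.stack([k_phi.values[:, c], k_gamma.values[:, c]]))
                       for c in range(N_CHANNELS)])
            ca.append([cmc(np.stack([k_hat.values[:, c], k_gamma.values[:, c]]))
                       for c in range(N_CHANNELS)])
        results.append(FoldResult(
            subject_id=held_out, task=task,
            inputs=inputs, targets=targets, refined=refined,
            rmse_before=np.asarray(rb), rmse_after=np.asarray(ra),
            cmc_before=np.asarray(cb), cmc_after=np.asarray(ca),
            model=model if keep_models else None))
    covered = {r.subject_id for r in results}
    if covered != set(subjects):
        raise RuntimeError("LOOCV folds do not cover every subject exactly once")
    return results
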