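"""CNN regression from 150-bp DNA sequence to change in CTCF binding,
with chromosome-holdout evaluation and reference-based attribution.

The network — four 1D convolutions (128, 128, 128, 64 filters of widths
5, 3, 5, 3; 'same' padding), each followed by ReLU and max-pool of 2,
then dense layers of 128 and 64 units with ReLU and dropout 0.4, and a
single linear output — is trained with mean-squared-error loss and Adam
(batch 64), early-stopping on a 20 % validation split with patience 15.
The sequence axis shrinks 150 -> 75 -> 37 -> 18 -> 9 through the pools.

The implementation is plain NumPy: convolutions are im2col matrix
products, and the hand-written backward pass also yields gradients with
respect to the input one-hot encoding, which drive the expected-gradients
attribution (averaging (x - ref) * grad f along the interpolation path
against dinucleotide-shuffled reference sequences).  In-silico
mutagenesis (ISM) is the model-agnostic attribution oracle.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class ModelSpec:
    input_length: int = 150
    conv_filters: tuple = (128, 128, 128, 64)
    conv_kernels: tuple = (5, 3, 5, 3)
    pool_size: int = 2
    dense_units: tuple = (128, 64)
    dropout: float = 0.4
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 15
    max_epochs: int = 30
    validation_fraction: float = 0.2


@dataclass
class SplitSpec:
    holdout_chroms: tuple = ("chr16", "chr17", "chr18", "chr19")


@dataclass
class TrainingReport:
    train_loss: list
    val_loss: list
    stopped_epoch: int
    best_epoch: int
    test_pearson_r: float | None = None
    test_mse: float | None = None
    zero_label_variance: bool = False


# ---------------------------------------------------------------------------
# Encoding


def one_hot(sequence: str, length: int = 150) -> np.ndarray:
    """(length, 4) one-hot; N columns are all-zero."""
    if len(sequence) != length:
        raise ValueError(f"sequence length {len(sequence)} != {length}")
    out = np.zeros((length, 4), dtype=np.float32)
    for i, base in enumerate(sequence.upper()):
        j = _BASE_INDEX.get(base)
        if j is not None:
            out[i, j] = 1.0
    return out


def one_hot_decode(encoded: np.ndarray) -> str:
    out = []
    for col in encoded:
        if col.sum() == 0:
            out.append("N")
        else:
            out.append(BASES[int(np.argmax(col))])
    return "".join(out)


def encode_batch(sequences, length: int = 150) -> np.ndarray:
    return np.stack([one_hot(s, length) for s in sequences])


# ---------------------------------------------------------------------------
# Layers (forward + backward, float32, gemm-based convolutions)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L, k*C) patches with 'same' zero padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    # win: (B, L, C, k) -> (B, L, k, C)
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1], k * x.shape[2]
    )


class Conv1D:
    def __init__(self, k, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (k * c_in))
        self.W = (rng.standard_normal((k, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.c_in, self.c_out = k, c_in, c_out

    def forward(self, x, cache=None):
        patches = _im2col(x, self.k)
        y = patches @ self.W.reshape(self.k * self.c_in, self.c_out) + self.b
        if cache is not None:
            cache["patches"] = patches
        return y

    def backward(self, dy, cache, grads):
        B, L, _ = dy.shape
        patches = cache["patches"].reshape(B * L, -1)
        dyf = dy.reshape(B * L, self.c_out)
        grads["W"] = (patches.T @ dyf).reshape(self.W.shape)
        grads["b"] = dyf.sum(axis=0)
        # dx via 'full' correlation with the flipped kernel
        dpatches = _im2col(dy, self.k)  # (B, L, k*c_out)
        Wrev = np.ascontiguousarray(
            self.W[::-1].transpose(0, 2, 1)
        ).reshape(self.k * self.c_out, self.c_in)
        return dpatches @ Wrev

    def params(self):
        return {"W": self.W, "b": self.b}


class Dense:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, cache=None):
        if cache is not None:
            cache["x"] = x
        return x @ self.W + self.b

    def backward(self, dy, cache, grads):
        grads["W"] = cache["x"].T @ dy
        grads["b"] = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}


def _relu_forward(x, cache=None):
    if cache is not None:
        cache["mask"] = x > 0
    return np.maximum(x, 0)


def _maxpool_forward(x, cache=None):
    B, L, C = x.shape
    L2 = L // 2
    a = x[:, : 2 * L2 : 2]
    b = x[:, 1 : 2 * L2 : 2]
    take_a = a >= b  # ties go to the first element, deterministically
    if cache is not None:
        cache["take_a"] = take_a
        cache["in_shape"] = x.shape
    return np.where(take_a, a, b)


def _maxpool_backward(dy, cache):
    B, L, C = cache["in_shape"]
    L2 = dy.shape[1]
    dx = np.zeros((B, L, C), dtype=dy.dtype)
    take_a = cache["take_a"]
    dx[:, : 2 * L2 : 2] = np.where(take_a, dy, 0)
    dx[:, 1 : 2 * L2 : 2] = np.where(take_a, 0, dy)
    return dx


class CNNRegressor:
    """Sequence-to-scalar convolutional regressor (see module docstring)."""

    def __init__(self, spec: ModelSpec | None = None, seed: int = 0):
        self.spec = spec or ModelSpec()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
        s = self.spec
        self.convs = []
        c_in = 4
        length = s.input_length
        for f, k in zip(s.conv_filters, s.conv_kernels):
            self.convs.append(Conv1D(k, c_in, f, rng))
            c_in = f
            length = length // s.pool_size
        self.flat_dim = length * c_in
        self.denses = []
        n_in = self.flat_dim
        for units in s.dense_units:
            self.denses.append(Dense(n_in, units, rng))
            n_in = units
        self.out_layer = Dense(n_in, 1, rng)
        self.trained = False
        self._rng = rng

    # -- forward / backward ------------------------------------------------

    def _forward(self, x, train=False, caches=None, dropout_rng=None):
        h = x
        for li, conv in enumerate(self.convs):
            cache = {} if caches is not None else None
            h = conv.forward(h, cache)
            if cache is not None:
                caches.append(("conv", conv, cache))
            rc = {} if caches is not None else None
            h = _relu_forward(h, rc)
            if rc is not None:
                caches.append(("relu", None, rc))
            pc = {} if caches is not None else None
            h = _maxpool_forward(h, pc)
            if pc is not None:
                caches.append(("pool", None, pc))
        B = h.shape[0]
        shape = h.shape
        h = h.reshape(B, -1)
        if caches is not None:
            caches.append(("flatten", None, {"shape": shape}))
        for dense in self.denses:
            cache = {} if caches is not None else None
            h = dense.forward(h, cache)
            if cache is not None:
                caches.append(("dense", dense, cache))
            rc = {} if caches is not None else None
            h = _relu_forward(h, rc)
            if rc is not None:
                caches.append(("relu", None, rc))
            if train and self.spec.dropout > 0:
                keep = 1.0 - self.spec.dropout
                mask = (dropout_rng.random(h.shape) < keep).astype(np.float32) / keep
                h = h * mask
                if caches is not None:
                    caches.append(("dropout", None, {"mask": mask}))
        cache = {} if caches is not None else None
        y = self.out_layer.forward(h, cache)
        if cache is not None:
            caches.append(("dense", self.out_layer, cache))
        return y[:, 0]

    def _backward(self, dy, caches, collect_input_grad=False):
        """dy: (B,) gradient at the output; returns (param_grads, dx)."""
        g = dy[:, None].astype(np.float32)
        param_grads = []
        for kind, layer, cache in reversed(caches):
            if kind == "dense":
                grads = {}
                g = layer.backward(g, cache, grads)
                param_grads.append((layer, grads))
            elif kind == "conv":
                grads = {}
                g = layer.backward(g, cache, grads)
                param_grads.append((layer, grads))
            elif kind == "relu":
                g = g * cache["mask"]
            elif kind == "pool":
                g = _maxpool_backward(g, cache)
            elif kind == "dropout":
                g = g * cache["mask"]
            elif kind == "flatten":
                g = g.reshape(cache["shape"])
        dx = g if collect_input_grad else None
        return param_grads, dx

    # -- public API --------------------------------------------------------

    def predict(self, X, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = []
        for i in range(0, len(X), batch_size):
            out.append(self._forward(X[i : i + batch_size], train=False))
        return np.concatenate(out) if out else np.zeros(0)

    def input_gradients(self, X, batch_size: int = 256) -> np.ndarray:
        """d f / d x for each input, via the full backward pass (no dropout)."""
        X = np.asarray(X, dtype=np.float32)
        out = []
        for i in range(0, len(X), batch_size):
            caches = []
            xb = X[i : i + batch_size]
            self._forward(xb, train=False, caches=caches)
            _, dx = self._backward(
                np.ones(len(xb), dtype=np.float32), caches, collect_input_grad=True
            )
            out.append(dx)
        return np.concatenate(out) if out else np.zeros((0,) + X.shape[1:])

    def _adam_state(self):
        state = []
        for layer in [*self.convs, *self.denses, self.out_layer]:
            state.append(
                {
                    name: (np.zeros_like(p), np.zeros_like(p))
                    for name, p in layer.params().items()
                }
            )
        return state

    def fit(self, X, y, seed: int = 0, verbose: bool = False) -> TrainingReport:
        s = self.spec
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
        drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 203]))
        zero_var = bool(np.std(y) == 0)

        n = len(X)
        n_val = max(1, int(round(s.validation_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        layers = [*self.convs, *self.denses, self.out_layer]
        adam = {id(l): {k: [np.zeros_like(p), np.zeros_like(p)] for k, p in l.params().items()} for l in layers}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_val = np.inf
        best_state = None
        best_epoch = 0
        train_losses, val_losses = [], []
        epoch = 0
        for epoch in range(1, s.max_epochs + 1):
            order = rng.permutation(len(Xtr))
            total = 0.0
            for i in range(0, len(Xtr), s.batch_size):
                idx = order[i : i + s.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                caches = []
                pred = self._forward(xb, train=True, caches=caches, dropout_rng=drop_rng)
                err = pred - yb
                total += float((err**2).sum())
                dy = (2.0 / len(xb)) * err
                param_grads, _ = self._backward(dy, caches)
                t += 1
                lr_t = s.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                for layer, grads in param_grads:
                    st = adam[id(layer)]
                    for name, gval in grads.items():
                        m, v = st[name]
                        m *= beta1
                        m += (1 - beta1) * gval
                        v *= beta2
                        v += (1 - beta2) * gval**2
                        layer.params()[name] -= lr_t * m / (np.sqrt(v) + eps)
            train_losses.append(total / len(Xtr))
            val_pred = self.predict(Xval)
            val_loss = float(np.mean((val_pred - yval) ** 2))
            val_losses.append(val_loss)
            if verbose:
                print(f"epoch {epoch}: train {train_losses[-1]:.4f} val {val_loss:.4f}")
            if val_loss < best_val - 1e-7:
                best_val = val_loss
                best_epoch = epoch
                best_state = [
                    {k: p.copy() for k, p in l.params().items()} for l in layers
                ]
            elif epoch - best_epoch >= s.patience:
                break
        if best_state is not None:
            for layer, state in zip(layers, best_state):
                for k, p in layer.params().items():
                    p[...] = state[k]
        self.trained = True
        return TrainingReport(
            train_loss=train_losses,
            val_loss=val_losses,
            stopped_epoch=epoch,
            best_epoch=best_epoch,
            zero_label_variance=zero_var,
        )

    def parameter_shapes(self) -> list[tuple]:
        shapes = []
        for layer in [*self.convs, *self.denses, self.out_layer]:
            for name, p in layer.params().items():
                shapes.append((type(layer).__name__, name, p.shape))
        return shapes


# ---------------------------------------------------------------------------
# Training protocol


def train_model(
    sequences,
    labels,
    chroms,
    split: SplitSpec | None = None,
    spec: ModelSpec | None = None,
    seed: int = 0,
    verbose: bool = False,
):
    """Train with chromosome holdout and report test-set performance.

    Sites on ``split.holdout_chroms`` are excluded from training and
    validation and kept as the test set.  Returns (model, report,
    test_mask).
    """
    from scipy.stats import pearsonr

    split = split or SplitSpec()
    spec = spec or ModelSpec()
    labels = np.asarray(labels, dtype=float)
    if not np.all(np.isfinite(labels)):
        raise ValueError("labels must be finite")
    chroms = np.asarray(chroms)
    test_mask = np.isin(chroms, list(split.holdout_chroms))
    if not test_mask.any():
        raise ValueError("holdout set is empty")
    X = encode_batch(sequences, spec.input_length)
    model = CNNRegressor(spec, seed=seed)
    report = model.fit(X[~test_mask], labels[~test_mask], seed=seed, verbose=verbose)
    test_pred = model.predict(X[test_mask])
    report.test_mse = float(np.mean((test_pred - labels[test_mask]) ** 2))
    if np.std(test_pred) > 0 and np.std(labels[test_mask]) > 0:
        report.test_pearson_r = float(pearsonr(test_pred, labels[test_mask])[0])
    else:
        report.test_pearson_r = 0.0
    return model, report, test_mask


# ---------------------------------------------------------------------------
# Dinucleotide shuffling (Altschul–Erickson Euler-path shuffle)


def dinucleotide_shuffle(sequence: str, n_shuffles: int = 1, seed: int = 0) -> list[str]:
    """Shuffles preserving the exact dinucleotide count multiset.

    Implements the Euler-path algorithm: pick a random last-exit edge set
    forming an arborescence into the final vertex, then randomize the
    order of the remaining exits.  Runs of N split the sequence into
    segments shuffled independently.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    seq = sequence.upper()
    if "N" in seq:
        parts = []
        current = []
        for ch in seq:
            if ch == "N":
                if current:
                    parts.append("".join(current))
                    current = []
                parts.append("N")
            else:
                current.append(ch)
        if current:
            parts.append("".join(current))
        out = []
        for _ in range(n_shuffles):
            out.append(
                "".join(p if p == "N" else _euler_shuffle(p, rng) for p in parts)
            )
        return out
    return [_euler_shuffle(seq, rng) for _ in range(n_shuffles)]


def _euler_shuffle(seq: str, rng) -> str:
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    for _ in range(1000):
        # choose a random last-exit edge per vertex (except the final one)
        last_exit = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            last_exit[v] = edges[v][rng.integers(len(edges[v]))]
        if _connects_to_last(last_exit, last):
            break
    else:  # pragma: no cover - astronomically unlikely on DNA alphabets
        raise RuntimeError("failed to sample an Eulerian last-exit tree")
    # shuffle the non-last-exit edges of each vertex, append the last exit
    pools = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_exit:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        if v in last_exit:
            pool.append(last_exit[v])
        pools[v] = pool
    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    v = seq[0]
    for _ in range(len(seq) - 1):
        nxt = pools[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def _connects_to_last(last_exit: dict, last: str) -> bool:
    for v in last_exit:
        seen = set()
        cur = v
        while cur in last_exit and cur not in seen:
            seen.add(cur)
            cur = last_exit[cur]
        if cur != last:
            return False
    return True


# ---------------------------------------------------------------------------
# Attribution


def attribute(
    model: CNNRegressor,
    sequences,
    method: str = "expected_gradients",
    n_references: int = 100,
    n_steps: int = 1,
    seed: int = 0,
    batch_refs: int = 100,
):
    """Per-sequence contribution tensors (n, length, 4).

    expected_gradients: E_ref,alpha[ (x - ref) * grad f(ref + alpha (x - ref)) ],
    references being dinucleotide shuffles of each sequence (completeness:
    contributions sum to f(x) - E[f(ref)] up to sampling error; raise
    ``n_steps`` to average several interpolation points per reference and
    tighten the path integral).
    ism: per-position, per-base score f(x) - f(x with base substituted);
    the observed base gets f(x) - mean over the three substitutions.
    """
    if not model.trained:
        raise RuntimeError("model is untrained; fit it before attribution")
    if method == "ism":
        return _ism_attribution(model, sequences)
    if method != "expected_gradients":
        raise ValueError(f"unknown attribution method {method!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    length = model.spec.input_length
    out = np.zeros((len(sequences), length, 4), dtype=np.float64)
    for i, seq in enumerate(sequences):
        x = one_hot(seq, length)
        refs = dinucleotide_shuffle(seq, n_shuffles=n_references, seed=seed + 7 * i + 1)
        R = encode_batch(refs, length)
        # stratified interpolation coefficients: jittered alphas covering
        # [0, 1) evenly across references (and steps), which keeps the
        # path integral well sampled at any n_references
        acc = np.zeros((length, 4))
        for _ in range(n_steps):
            u = (np.arange(n_references) + rng.random(n_references)) / n_references
            alphas = rng.permutation(u).astype(np.float32)[:, None, None]
            interp = R + alphas * (x[None] - R)
            grads = model.input_gradients(interp, batch_size=batch_refs)
            acc += ((x[None] - R) * grads).mean(axis=0)
        out[i] = acc / n_steps
    return out


def _ism_attribution(model: CNNRegressor, sequences):
    length = model.spec.input_length
    out = np.zeros((len(sequences), length, 4), dtype=np.float64)
    for i, seq in enumerate(sequences):
        x = one_hot(seq, length)
        f0 = float(model.predict(x[None])[0])
        variants = []
        slots = []
        for p in range(length):
            for b in range(4):
                if x[p, b] == 1.0:
                    continue
                xv = x.copy()
                xv[p] = 0.0
                xv[p, b] = 1.0
                variants.append(xv)
                slots.append((p, b))
        preds = model.predict(np.stack(variants)) if variants else np.zeros(0)
        delta = np.zeros((length, 4))
        for (p, b), fv in zip(slots, preds):
            delta[p, b] = f0 - fv
        for p in range(length):
            obs = np.argmax(x[p]) if x[p].sum() else None
            if obs is not None:
                others = [b for b in range(4) if b != obs]
                delta[p, obs] = np.mean([delta[p, b] for b in others])
        out[i] = delta
    return out


def per_position_scores(tensors: np.ndarray, sequences) -> np.ndarray:
    """Contribution of the observed base at each position, (n, length)."""
    n, length, _ = tensors.shape
    out = np.zeros((n, length))
    for i, seq in enumerate(sequences):
        for p, base in enumerate(seq.upper()):
            j = _BASE_INDEX.get(base)
            if j is not None:
                out[i, p] = tensors[i, p, j]
    return out


def contribution_weight_matrix(tensors: np.ndarray, sequences):
    """CWM: cell (base, p) = mean contribution at p over sequences whose
    observed base at p is that base; cells never observed are NaN."""
    n, length, _ = tensors.shape
    total = np.zeros((4, length))
    count = np.zeros((4, length))
    for i, seq in enumerate(sequences):
        for p, base in enumerate(seq.upper()):
            j = _BASE_INDEX.get(base)
            if j is None:
                continue
            total[j, p] += tensors[i, p, j]
            count[j, p] += 1
    with np.errstate(invalid="ignore"):
        cwm = total / count
    cwm[count == 0] = np.nan
    return cwm


def cwm_mass_fraction(cwm: np.ndarray, windows) -> float:
    """Fraction of total absolute CWM mass inside the given position
    windows (list of (start, end) half-open column ranges)."""
    mass = np.nansum(np.abs(cwm), axis=0)
    total = mass.sum()
    if total == 0:
        return 0.0
    inside = sum(mass[s:e].sum() for s, e in windows)
    return float(inside / total)


def m2_site_scan(sequences, m2_pfm, threshold_fraction: float = 0.8):
    """Scan oriented site windows for an M2 match.

    Returns (has_m2 flags, offsets) where offset is the hit start relative
    to the window center (the M1 center), or None without a hit.  Only the
    oriented (forward) strand is scanned: M2 has a fixed orientation
    relative to M1.
    """
    from .enrichment_binding import pwm_log_odds, encode_sequence

    lom = pwm_log_odds(np.asarray(m2_pfm, float))
    width = lom.shape[1]
    threshold = threshold_fraction * float(lom.max(axis=0).sum())
    flags = np.zeros(len(sequences), dtype=bool)
    offsets: list = []
    for i, seq in enumerate(sequences):
        enc = encode_sequence(seq)
        center = len(seq) // 2
        scores = np.zeros(len(seq) - width + 1)
        valid = np.ones(len(scores), dtype=bool)
        for k in range(width):
            col = enc[k : k + len(scores)]
            good = col < 4
            scores[good] += lom[col[good], k]
            valid &= good
        scores[~valid] = -np.inf
        best = int(np.argmax(scores))
        if scores[best] >= threshold:
            flags[i] = True
            offsets.append(best - center)
        else:
            offsets.append(None)
    return flags, offsets


def save_model(model: CNNRegressor, path) -> None:
    """Checkpoint: parameter arrays plus the JSON ModelSpec."""
    import json

    arrays = {}
    for li, layer in enumerate([*model.convs, *model.denses, model.out_layer]):
        for name, p in layer.params().items():
            arrays[f"layer{li}_{name}"] = p
    np.savez(path, **arrays)
    spec_path = str(path) + ".spec.json"
    with open(spec_path, "w") as fh:
        json.dump(model.spec.__dict__, fh, indent=1, default=list)


def load_model(path, spec: ModelSpec | None = None) -> CNNRegressor:
    import json

    if spec is None:
        with open(str(path) + ".spec.json") as fh:
            d = json.load(fh)
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        spec = ModelSpec(**d)
    model = CNNRegressor(spec, seed=0)
    data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    for li, layer in enumerate([*model.convs, *model.denses, model.out_layer]):
        for name, p in layer.params().items():
            p[...] = data[f"layer{li}_{name}"]
    model.trained = True
    return model
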