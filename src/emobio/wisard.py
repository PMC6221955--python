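"""Weightless neural network (WiSARD) with bleaching, built from scratch.

Real-valued feature vectors are thermometer-encoded (per-feature min/max
fit on training data only), the resulting bit string is permuted by a
seeded mapping and partitioned into n-bit address tuples, and each class
owns one discriminator: a RAM node per tuple holding write counters.

Classification evaluates the discriminators at a bleaching threshold
``b`` (a tuple fires if its counter at the observed address is >= b),
starting at ``b = 1`` and raising it until a unique winner emerges.  If
every response has dropped to zero while still tied, ties break on the raw
``b = 1`` responses, then on lexicographic label order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Encoder", "fit_encoder", "WisardModel", "make_model", "train", "classify",
           "WisardClassifier"]


# ---------------------------------------------------------------------------
# thermometer encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Encoder:
    """Per-feature thermometer code: value -> leading ones in a bit ramp."""

    bits_per_feature: int
    mins: np.ndarray
    maxs: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.mins)

    @property
    def total_bits(self) -> int:
        return self.bits_per_feature * self.n_features

    def encode(self, X: np.ndarray) -> np.ndarray:
        """(n, d) reals -> (n, d * bits) uint8 in {0, 1}."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        span = self.maxs - self.mins
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(span > 0, (X - self.mins) / np.where(span > 0, span, 1.0), 0.0)
        frac = np.clip(frac, 0.0, 1.0)
        n_on = np.floor(self.bits_per_feature * frac).astype(int)
        ramp = np.arange(self.bits_per_feature)
        bits = (ramp[None, None, :] < n_on[:, :, None]).astype(np.uint8)
        return bits.reshape(X.shape[0], self.total_bits)


def fit_encoder(train_features: np.ndarray, bits: int = 16) -> Encoder:
    """Fit per-feature min/max on training rows only."""
    X = np.atleast_2d(np.asarray(train_features, dtype=float))
    if bits < 2:
        raise ValueError("bits_per_feature must be >= 2")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mins, maxs = X.min(axis=0), X.max(axis=0)
    if np.any(mins == maxs):
        warnings.warn("constant feature(s) in training data: their code is all-zero",
                      stacklevel=2)
    return Encoder(bits_per_feature=bits, mins=mins, maxs=maxs)


# ---------------------------------------------------------------------------
# RAM discriminators
# ---------------------------------------------------------------------------

@dataclass
class WisardModel:
    """Per-class RAM discriminators over a seeded bit-permutation mapping."""

    n_tuple: int
    mapping: np.ndarray  # permutation of padded bit indices, length = n_tuples * n_tuple
    n_bits: int  # un-padded input length
    seed: int
    discriminators: dict[str, list[dict[int, int]]] = field(default_factory=dict)

    @property
    def n_tuples(self) -> int:
        return len(self.mapping) // self.n_tuple

    @property
    def trained(self) -> bool:
        return bool(self.discriminators)

    def _addresses(self, bits: np.ndarray) -> np.ndarray:
        """Tuple addresses of one encoded example (padding bits read as 0)."""
        if len(bits) != self.n_bits:
            raise ValueError(f"expected {self.n_bits} bits, got {len(bits)}")
        padded = np.zeros(len(self.mapping), dtype=np.uint8)
        padded[: self.n_bits] = bits
        grouped = padded[self.mapping].reshape(self.n_tuples, self.n_tuple)
        weights = 1 << np.arange(self.n_tuple)
        return grouped @ weights

    # -- serialization ---------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "n_tuple": self.n_tuple,
            "n_bits": self.n_bits,
            "seed": self.seed,
            "mapping": self.mapping.tolist(),
            "discriminators": {
                label: [{str(a): c for a, c in ram.items()} for ram in rams]
                for label, rams in self.discriminators.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "WisardModel":
        with open(path) as fh:
            obj = json.load(fh)
        model = cls(
            n_tuple=obj["n_tuple"],
            mapping=np.asarray(obj["mapping"], dtype=int),
            n_bits=obj["n_bits"],
            seed=obj["seed"],
        )
        model.discriminators = {
            label: [{int(a): c for a, c in ram.items()} for ram in rams]
            for label, rams in obj["discriminators"].items()
        }
        return model


def make_model(n_bits: int, n_tuple: int = 4, seed: int = 0) -> WisardModel:
    """Untrained model with a seeded bit-permutation mapping.

    Input length not divisible by ``n_tuple`` is padded with always-zero
    bits so every tuple is complete.
    """
    if n_tuple < 1 or n_bits < 1:
        raise ValueError("n_bits and n_tuple must be >= 1")
    padded = int(np.ceil(n_bits / n_tuple)) * n_tuple
    rng = np.random.default_rng(seed)
    mapping = rng.permutation(padded)
    return WisardModel(n_tuple=n_tuple, mapping=mapping, n_bits=n_bits, seed=seed)


def train(model: WisardModel, encoded: np.ndarray, labels) -> WisardModel:
    """Write each example into its class's discriminator (counters += 1)."""
    encoded = np.atleast_2d(np.asarray(encoded))
    labels = np.asarray(labels)
    for bits, label in zip(encoded, labels, strict=True):
        rams = model.discriminators.setdefault(
            str(label), [dict() for _ in range(model.n_tuples)]
        )
        for ram, addr in zip(rams, model._addresses(bits)):
            ram[int(addr)] = ram.get(int(addr), 0) + 1
    return model


def responses_at(model: WisardModel, encoded_vec: np.ndarray, b: int) -> dict[str, int]:
    """Per-class count of tuples whose counter at the observed address >= b."""
    addrs = model._addresses(np.asarray(encoded_vec))
    return {
        label: sum(ram.get(int(a), 0) >= b for ram, a in zip(rams, addrs))
        for label, rams in model.discriminators.items()
    }


def classify(model: WisardModel, encoded_vec: np.ndarray) -> tuple[str, dict[str, int], int]:
    """Predict with bleaching; returns (label, responses at the final b, b)."""
    if not model.trained:
        raise ValueError("model has no trained discriminators")
    raw = responses_at(model, encoded_vec, 1)
    b = 1
    resp = raw
    while True:
        top = max(resp.values())
        winners = [lab for lab, r in resp.items() if r == top]
        if len(winners) == 1:
            return winners[0], resp, b
        if top == 0:
            break
        b += 1
        resp = responses_at(model, encoded_vec, b)
    # persistent tie at zero response: fall back to raw responses, then label order
    top_raw = max(raw[lab] for lab in winners)
    winners = sorted(lab for lab in winners if raw[lab] == top_raw)
    return winners[0], resp, b


# ---------------------------------------------------------------------------
# sklearn-style convenience wrapper
# ---------------------------------------------------------------------------

class WisardClassifier:
    """fit/predict wrapper: thermometer encoding + RAM training + bleaching."""

    def __init__(self, bits_per_feature: int = 16, n_tuple: int = 4, seed: int = 0):
        self.bits_per_feature = bits_per_feature
        self.n_tuple = n_tuple
        self.seed = seed
        self.encoder_: Encoder | None = None
        self.model_: WisardModel | None = None

    def fit(self, X, y) -> "WisardClassifier":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.encoder_ = fit_encoder(X, bits=self.bits_per_feature)
        self.model_ = make_model(self.encoder_.total_bits, self.n_tuple, self.seed)
        train(self.model_, self.encoder_.encode(X), y)
        return self

    def predict(self, X) -> np.ndarray:
        if self.model_ is None or self.encoder_ is None:
            raise ValueError("classifier is not fitted")
        enc = self.encoder_.encode(np.atleast_2d(np.asarray(X, dtype=float)))
        return np.array([classify(self.model_, row)[0] for row in enc])

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=str)))
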