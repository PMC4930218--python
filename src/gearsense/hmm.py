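"""Two-state hidden Markov model on vessel speed for trawler detection.

Trawlers tow their gear at slow, steady speeds (typically 2.5-5.5 knots)
and steam much faster between grounds, so speed over ground alone separates
the two behavioral states well.  The model is a supervised two-state HMM
with states NF (non-fishing) and F (fishing): the joint probability of a
state sequence S_1..T and observed speeds Y_1..T factorizes as

    Pr(S_1) Pr(Y_1|S_1) * prod_{t=2..T} Pr(Y_t|S_t) Pr(S_t|S_{t-1})

All parameters are estimated directly from expert-labeled tracks: the
transition matrix from label-pair counts along each track, the initial
distribution from empirical state frequencies, and the per-state speed
emission either as a smoothed histogram (default; captures the skewed,
heavy-tailed empirical speed shapes) or as a Gaussian.  Decoding is Viterbi
(default) or per-point posterior argmax; ties break toward NF.

There is no unsupervised (Baum-Welch) training here by design: the model is
supervised by labels.
"""

from __future__ import annotations

import json
import logging
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .tracks import LABEL_FISHING, LABEL_NONFISHING, Track

logger = logging.getLogger(__name__)

#: Internal state order. Index 0 = NF so that argmax ties resolve toward NF.
STATES = (LABEL_NONFISHING, LABEL_FISHING)
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


def _as_sequences(X, y=None):
    """Normalize input to (list of 1-D speed arrays, list of label arrays)."""
    first = X[0] if len(X) else None
    if first is not None and np.ndim(first) == 0:
        X = [X]
        y = [y] if y is not None else None
    seqs = [np.asarray(s, dtype=float).ravel() for s in X]
    if y is None:
        return seqs, None
    labs = [np.asarray(l, dtype=object).ravel() for l in y]
    if len(labs) != len(seqs) or any(len(a) != len(b) for a, b in zip(seqs, labs)):
        raise ValueError("speed sequences and label sequences must align")
    return seqs, labs


class TrawlerHMM(BaseEstimator, ClassifierMixin):
    """Supervised two-state speed HMM for fishing/non-fishing decoding.

    Parameters
    ----------
    emission : {"histogram", "gaussian"}
        Per-state emission family for speed. The histogram uses bins of
        ``bin_width`` knots on [0, v_max] with ``alpha`` pseudo-counts;
        speeds at or above ``v_max`` fall in the top bin (AIS speed fields
        saturate around 25.5 kn, hence the default ceiling).
    bin_width : float, knots.
    v_max : float, knots.
    alpha : float
        Additive smoothing pseudo-count per histogram bin.
    decode_method : {"viterbi", "posterior"}
        Default decoding: global argmax path vs per-point marginal argmax.
    log_floor : float
        Floor for log-emission of zero-probability observations (possible
        with ``alpha=0``); floored lookups are logged.

    Attributes
    ----------
    pi_ : (2,) ndarray — initial distribution over (NF, F).
    transmat_ : (2, 2) ndarray — row-stochastic transition matrix.
    bin_edges_, emission_probs_ : histogram emission (if selected).
    means_, sds_ : Gaussian emission (if selected).
    classes_ : ("NF", "F").
    """

    def __init__(
        self,
        emission: str = "histogram",
        bin_width: float = 0.5,
        v_max: float = 25.5,
        alpha: float = 1.0,
        decode_method: str = "viterbi",
        log_floor: float = -30.0,
    ):
        self.emission = emission
        self.bin_width = bin_width
        self.v_max = v_max
        self.alpha = alpha
        self.decode_method = decode_method
        self.log_floor = log_floor

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        """Estimate pi, transitions and emissions from labeled sequences.

        ``X``: one 1-D speed array or a list of them (one per track);
        ``y``: matching activity labels in {"F", "NF"}.  Transitions are
        counted within each track only, never across track boundaries.
        """
        seqs, labs = _as_sequences(X, y)
        if labs is None:
            raise ValueError("supervised fit requires labels")
        all_labels = np.concatenate(labs) if labs else np.array([], dtype=object)
        if all_labels.size == 0:
            raise ValueError("no training points")
        bad = set(all_labels) - set(STATES)
        if bad:
            raise ValueError(f"labels outside {{F, NF}}: {sorted(map(str, bad))}")
        for s in STATES:
            if not np.any(all_labels == s):
                raise ValueError(f"state {s!r} absent from training labels")

        states = [np.array([_STATE_INDEX[l] for l in lab]) for lab in labs]
        counts = np.zeros((2, 2))
        for st in states:
            if len(st) >= 2:
                np.add.at(counts, (st[:-1], st[1:]), 1.0)
        if counts.sum() == 0:
            raise ValueError("no observed transitions (all tracks length 1)")
        row = counts.sum(axis=1, keepdims=True)
        # a state never in first position of a pair: fall back to staying put
        self.transmat_ = np.where(row > 0, counts / np.where(row == 0, 1, row), np.eye(2))
        flat = np.concatenate(states)
        self.pi_ = np.array([(flat == 0).mean(), (flat == 1).mean()])

        speeds = np.concatenate(seqs)
        if self.emission == "histogram":
            n_bins = int(np.ceil(self.v_max / self.bin_width))
            self.bin_edges_ = np.arange(n_bins + 1, dtype=float) * self.bin_width
            probs = np.empty((2, n_bins))
            for si in range(2):
                idx = self._bin_index(speeds[flat == si])
                c = np.bincount(idx, minlength=n_bins).astype(float) + self.alpha
                probs[si] = c / c.sum()
            self.emission_probs_ = probs
        elif self.emission == "gaussian":
            self.means_ = np.empty(2)
            self.sds_ = np.empty(2)
            for si in range(2):
                v = speeds[flat == si]
                self.means_[si] = v.mean()
                sd = v.std(ddof=1) if len(v) > 1 else 0.0
                self.sds_[si] = max(sd, 1e-6)
        else:
            raise ValueError(f"unknown emission family {self.emission!r}")
        self.classes_ = np.array(STATES, dtype=object)
        return self

    # -- emission ----------------------------------------------------------

    def _bin_index(self, speeds: np.ndarray) -> np.ndarray:
        n_bins = int(np.ceil(self.v_max / self.bin_width))
        idx = np.floor(np.asarray(speeds, dtype=float) / self.bin_width).astype(int)
        return np.clip(idx, 0, n_bins - 1)

    def _log_emission(self, speeds: np.ndarray) -> np.ndarray:
        """(T, 2) log Pr(Y_t | S_t), floored at ``log_floor``."""
        speeds = np.asarray(speeds, dtype=float)
        if self.emission == "histogram":
            idx = self._bin_index(speeds)
            p = self.emission_probs_[:, idx].T  # (T, 2)
        else:
            from scipy.stats import norm

            p = np.column_stack(
                [norm.pdf(speeds, self.means_[s], self.sds_[s]) for s in range(2)]
            )
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        n_floored = int(np.sum(logp < self.log_floor))
        if n_floored:
            logger.info("floored %d zero/negligible emission log-probabilities", n_floored)
        return np.maximum(logp, self.log_floor)

    # -- inference ---------------------------------------------------------

    def decode(self, speeds, method: Optional[str] = None) -> np.ndarray:
        """Per-point state labels for one speed sequence."""
        method = method or self.decode_method
        speeds = np.asarray(speeds, dtype=float).ravel()
        if speeds.size == 0:
            raise ValueError("empty observation sequence")
        if method == "viterbi":
            path = self._viterbi(speeds)
        elif method == "posterior":
            gamma = self._posteriors(speeds)
            path = np.argmax(gamma, axis=1)  # index 0 = NF wins ties
        else:
            raise ValueError(f"unknown decode method {method!r}")
        return np.array([STATES[i] for i in path], dtype=object)

    def predict(self, X, method: Optional[str] = None):
        """Decode one sequence (1-D input) or a list of sequences."""
        if len(X) and np.ndim(X[0]) != 0:
            return [self.decode(s, method=method) for s in X]
        return self.decode(X, method=method)

    def predict_proba(self, speeds) -> np.ndarray:
        """(T, 2) smoothed posterior marginals over (NF, F)."""
        return self._posteriors(np.asarray(speeds, dtype=float).ravel())

    def _viterbi(self, speeds: np.ndarray) -> np.ndarray:
        log_e = self._log_emission(speeds)
        with np.errstate(divide="ignore"):
            log_pi = np.maximum(np.log(self.pi_), self.log_floor)
            log_A = np.maximum(np.log(self.transmat_), self.log_floor)
        T = len(speeds)
        delta = np.empty((T, 2))
        psi = np.zeros((T, 2), dtype=int)
        delta[0] = log_pi + log_e[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + log_A  # cand[i, j]
            psi[t] = np.argmax(cand, axis=0)  # ties -> NF (index 0)
            delta[t] = cand[psi[t], np.arange(2)] + log_e[t]
        path = np.empty(T, dtype=int)
        path[-1] = int(np.argmax(delta[-1]))
        for t in range(T - 2, -1, -1):
            path[t] = psi[t + 1][path[t + 1]]
        return path

    def _posteriors(self, speeds: np.ndarray) -> np.ndarray:
        log_e = self._log_emission(speeds)
        e = np.exp(log_e)
        T = len(speeds)
        alpha = np.empty((T, 2))
        c = np.empty(T)
        alpha[0] = self.pi_ * e[0]
        c[0] = alpha[0].sum() or 1.0
        alpha[0] /= c[0]
        for t in range(1, T):
            alpha[t] = (alpha[t - 1] @ self.transmat_) * e[t]
            c[t] = alpha[t].sum() or 1.0
            alpha[t] /= c[t]
        beta = np.empty((T, 2))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[t] = self.transmat_ @ (e[t + 1] * beta[t + 1])
            beta[t] /= c[t + 1]
        gamma = alpha * beta
        gamma /= np.maximum(gamma.sum(axis=1, keepdims=True), 1e-300)
        return gamma

    def log_joint(self, states: Sequence[str], speeds) -> float:
        """Log joint probability of a (state sequence, speed sequence) pair.

        log Pr(S_1) + log Pr(Y_1|S_1) + sum_t [log Pr(S_t|S_{t-1}) +
        log Pr(Y_t|S_t)].  Zero-probability factors are floored at
        ``log_floor``.
        """
        speeds = np.asarray(speeds, dtype=float).ravel()
        if len(states) != len(speeds):
            raise ValueError("states and speeds must have equal length >= 1")
        if len(states) == 0:
            raise ValueError("empty sequence")
        idx = np.array([_STATE_INDEX[s] for s in states])
        log_e = self._log_emission(speeds)
        with np.errstate(divide="ignore"):
            log_pi = np.maximum(np.log(self.pi_), self.log_floor)
            log_A = np.maximum(np.log(self.transmat_), self.log_floor)
        total = log_pi[idx[0]] + log_e[0, idx[0]]
        for t in range(1, len(idx)):
            total += log_A[idx[t - 1], idx[t]] + log_e[t, idx[t]]
        return float(total)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        """Serialize parameters and fitted arrays to a JSON document."""
        doc = {
            "model": "gearsense.TrawlerHMM",
            "states": list(STATES),
            "params": self.get_params(),
            "pi": self.pi_.tolist(),
            "transmat": self.transmat_.tolist(),
        }
        if self.emission == "histogram":
            doc["bin_edges"] = self.bin_edges_.tolist()
            doc["emission_probs"] = self.emission_probs_.tolist()
        else:
            doc["means"] = self.means_.tolist()
            doc["sds"] = self.sds_.tolist()
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrawlerHMM":
        doc = json.loads(text)
        model = cls(**doc["params"])
        model.pi_ = np.array(doc["pi"])
        model.transmat_ = np.array(doc["transmat"])
        if model.emission == "histogram":
            model.bin_edges_ = np.array(doc["bin_edges"])
            model.emission_probs_ = np.array(doc["emission_probs"])
        else:
            model.means_ = np.array(doc["means"])
            model.sds_ = np.array(doc["sds"])
        model.classes_ = np.array(STATES, dtype=object)
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TrawlerHMM":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


# -- track-level convenience wrappers ---------------------------------------

def fit_tracks(tracks: Sequence[Track], **params) -> TrawlerHMM:
    """Fit a :class:`TrawlerHMM` from fully labeled tracks."""
    X, y = [], []
    for tr in tracks:
        if "label" not in tr.points.columns or tr.points["label"].isna().any():
            raise ValueError(f"track {tr.vessel_id!r} is not fully labeled")
        X.append(tr.points["sog"].to_numpy(dtype=float))
        y.append(tr.points["label"].to_numpy(dtype=object))
    return TrawlerHMM(**params).fit(X, y)


def decode_track(
    model: TrawlerHMM,
    track: Track,
    method: Optional[str] = None,
    offshore_km: Optional[float] = None,
) -> Track:
    """Return a copy of the track with HMM-predicted labels.

    If ``offshore_km`` is given and the track carries ``shore_km``, points
    closer to shore than the threshold are forced to NF after decoding (the
    coastal exclusion mask; optional because the HMM itself uses speed only).
    """
    labels = model.decode(track.points["sog"].to_numpy(dtype=float), method=method)
    out = track.copy()
    out.points["label"] = labels
    if offshore_km is not None and "shore_km" in out.points.columns:
        near = out.points["shore_km"].to_numpy(dtype=float) < offshore_km
        out.points.loc[near, "label"] = LABEL_NONFISHING
    return out
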