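"""Trainable nucleosome occupancy likelihood (NOL) scorer.

The scorer is a linear max-margin classifier over k-mer composition
features of 50 bp windows, trained on nucleosome-forming (positive) versus
nucleosome-inhibitory (negative) sequence sets.  Scores follow the NOL sign
convention: positive = nucleosome forming, negative = inhibitory.  Applied
to a longer sequence it slides the 50 bp window in 1 bp steps and assigns
each window's score to the window's center base (0-based window offset 25).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .genome_io import SignalTrack, reverse_complement

WINDOW = 50  #: scored window width in bp
CENTER = 25  #: 0-based offset within the window that receives the score

#: weights are snapped to this dyadic grid (2**-32) so every score is an
#: exactly representable dyadic rational: sliding-window scoring (int64
#: accumulation) and per-window dot products agree bit-for-bit, and a
#: window's score does not depend on the surrounding sequence it was
#: scored within
WEIGHT_SCALE = 2 ** 32


def _quantize(x):
    return np.round(np.asarray(x, dtype=float) * WEIGHT_SCALE) / WEIGHT_SCALE

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A,C,G,T -> 0..3; anything else -> -1."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_feature_names(k_max: int) -> list[str]:
    names = []
    for k in range(1, k_max + 1):
        alpha = ["A", "C", "G", "T"]
        kmers = [""]
        for _ in range(k):
            kmers = [p + b for p in kmers for b in alpha]
        names.extend(kmers)
    return names


def _kmer_ids(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(ids, valid) for all k-mers of a coded sequence; invalid ids are 0."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j:j + n]
        ids = ids * 4 + np.where(c < 0, 0, c)
        valid &= c >= 0
    return ids, valid


def featurize(seq: str, k_max: int = 3) -> np.ndarray:
    """k-mer count vector (k = 1..k_max, concatenated, lexicographic ACGT).

    The input must be exactly 50 bp of unambiguous A/C/G/T; windows with
    other letters are the caller's to mask, not to impute.  For each k the
    block of counts sums to 50 - k + 1.
    """
    if len(seq) != WINDOW:
        raise ValueError(f"expected a {WINDOW}-mer, got length {len(seq)}")
    codes = encode_bases(seq.upper())
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters; mask instead")
    parts = []
    for k in range(1, k_max + 1):
        ids, _ = _kmer_ids(codes, k)
        parts.append(np.bincount(ids, minlength=4 ** k).astype(float))
    return np.concatenate(parts)


@dataclass
class ScoreTrack:
    """Per-position scores with a validity mask.

    ``offsets`` are signed boundary-relative positions (or absolute
    positions for whole-sequence scoring); ``mask`` is True where a valid
    score exists (False at edge positions with no covering window and where
    any covering window contains a non-ACGT base).
    """

    offsets: np.ndarray
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.offsets) == len(self.values) == len(self.mask)):
            raise ValueError("offsets/values/mask length mismatch")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("non-finite score at an unmasked position")


class NucleosomeOccupancyModel(BaseEstimator, ClassifierMixin):
    """Linear SVM over k-mer composition of 50-mers, NOL sign convention.

    Parameters
    ----------
    k_max : int, default 3
        Largest k-mer length in the feature map (features are all k-mer
        counts for k = 1..k_max, position-independent).
    C : float, default 1.0
        SVM regularization constant; fixed, not tuned.
    strand_symmetric : bool, default False
        If True, features are averaged between a window and its reverse
        complement, making scores strand-invariant.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Linear decision weights, oriented so nucleosome-forming training
        examples score positive.
    intercept_ : float
    classes_ : ndarray, ``[-1, 1]`` (inhibitory, forming)
    training_meta_ : dict with n_pos, n_neg and the caller's seed.
    """

    def __init__(self, k_max: int = 3, C: float = 1.0,
                 strand_symmetric: bool = False):
        self.k_max = k_max
        self.C = C
        self.strand_symmetric = strand_symmetric

    # -- estimator API ------------------------------------------------------

    def _features(self, seqs) -> np.ndarray:
        rows = []
        for s in seqs:
            f = featurize(s, self.k_max)
            if self.strand_symmetric:
                f = 0.5 * (f + featurize(reverse_complement(s), self.k_max))
            rows.append(f)
        return np.asarray(rows)

    def fit(self, X, y, seed: int | None = None):
        """Fit on 50-mers ``X`` with labels ``y`` (+1 forming, -1/0 inhibitory)."""
        y = np.asarray([1 if v in (1, "+", "forming", True) else -1 for v in y])
        if len(set(map(str, X))) < 2 and len(np.unique(y)) > 1:
            raise ValueError("degenerate training: identical sequences in both classes")
        if len(np.unique(y)) < 2:
            raise ValueError("need both forming and inhibitory examples")
        pos = [s for s, lab in zip(X, y) if lab == 1]
        neg = [s for s, lab in zip(X, y) if lab == -1]
        if sorted(pos) == sorted(neg):
            raise ValueError("degenerate training: positive and negative sets identical")
        F = self._features(X)
        svm = SVC(kernel="linear", C=self.C)
        svm.fit(F, y)
        coef = svm.coef_.ravel().astype(float)
        intercept = float(svm.intercept_[0])
        # NOL sign convention: forming examples must score positive on average
        dec = F @ coef + intercept
        if dec[y == 1].mean() < dec[y == -1].mean():
            coef, intercept = -coef, -intercept
        self.coef_ = _quantize(coef)
        self.intercept_ = float(_quantize(intercept))
        self.classes_ = np.array([-1, 1])
        self.n_features_in_ = F.shape[1]
        self.training_meta_ = {"n_pos": len(pos), "n_neg": len(neg),
                               "seed": seed, "C": self.C, "k_max": self.k_max}
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._features(X) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)

    # -- NOL scoring --------------------------------------------------------

    def score_window(self, seq50: str) -> float:
        """NOL score of a single 50-mer."""
        return float(self.decision_function([seq50])[0])

    def _positional_scores(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """Window scores by window start (length L-49) and validity.

        Accumulation runs in int64 on the dyadic weight grid, so results
        are exact and independent of the scored sequence's extent.
        """
        codes = encode_bases(seq.upper())
        L = len(codes)
        n_win = L - WINDOW + 1
        base_ok = codes >= 0
        # window valid iff all 50 bases unambiguous
        ok_cum = np.concatenate(([0], np.cumsum(base_ok.astype(np.int64))))
        win_valid = (ok_cum[WINDOW:] - ok_cum[:-WINDOW]) == WINDOW
        total = np.zeros(n_win, dtype=np.int64)
        w_int = np.rint(self.coef_ * WEIGHT_SCALE).astype(np.int64)
        if L * max(1, np.abs(w_int).max()) >= 2 ** 62:
            raise OverflowError("sequence too long for exact accumulation")
        offset = 0
        for k in range(1, self.k_max + 1):
            n_feat = 4 ** k
            w = w_int[offset:offset + n_feat]
            offset += n_feat
            ids, valid = _kmer_ids(codes, k)
            per_pos = np.where(valid, w[ids], 0)
            span = WINDOW - k + 1  # k-mers per window
            cum = np.concatenate(([0], np.cumsum(per_pos)))
            total += cum[span:span + n_win] - cum[:n_win]
        return total / WEIGHT_SCALE + self.intercept_, win_valid

    def score_sliding(self, seq: str, offsets: np.ndarray | None = None) -> ScoreTrack:
        """Score every 50 bp window of ``seq``, center-assigned.

        The window starting at 0-based position i contributes its score to
        position i + 25; the first 25 and last 24 positions of the sequence
        carry no window center and are masked, as is any center whose
        window contains a non-ACGT base.  Equals brute-force per-window
        ``score_window`` exactly.
        """
        check_is_fitted(self, "coef_")
        L = len(seq)
        if L < WINDOW:
            raise ValueError(f"sequence shorter than the {WINDOW} bp window")
        scores, valid = self._positional_scores(seq)
        if self.strand_symmetric:
            rc_scores, rc_valid = self._positional_scores(reverse_complement(seq))
            scores = 0.5 * (scores + rc_scores[::-1])
            valid = valid & rc_valid[::-1]
        values = np.full(L, np.nan)
        mask = np.zeros(L, dtype=bool)
        centers = np.arange(L - WINDOW + 1) + CENTER
        values[centers] = scores
        mask[centers] = valid
        values[~mask] = np.nan
        if offsets is None:
            offsets = np.arange(L)
        return ScoreTrack(offsets=np.asarray(offsets), values=values, mask=mask)

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        check_is_fitted(self, "coef_")
        payload = {
            "format": "nolscan-model", "version": 1,
            "k_max": self.k_max, "C": self.C,
            "strand_symmetric": self.strand_symmetric,
            "feature_names": kmer_feature_names(self.k_max),
            "coef": self.coef_.tolist(), "intercept": self.intercept_,
            "training_meta": self.training_meta_,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "NucleosomeOccupancyModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        if payload.get("format") != "nolscan-model":
            raise ValueError("not a nolscan model file")
        model = cls(k_max=payload["k_max"], C=payload["C"],
                    strand_symmetric=payload["strand_symmetric"])
        model.coef_ = _quantize(payload["coef"])
        model.intercept_ = float(_quantize(payload["intercept"]))
        model.classes_ = np.array([-1, 1])
        model.n_features_in_ = len(model.coef_)
        model.training_meta_ = payload.get("training_meta", {})
        return model


def train(pos_seqs, neg_seqs, seed: int | None = None, *, k_max: int = 3,
          C: float = 1.0, strand_symmetric: bool = False) -> NucleosomeOccupancyModel:
    """Train a NOL model from forming (positive) / inhibitory (negative) 50-mers."""
    if not pos_seqs or not neg_seqs:
        raise ValueError("both training sets must be non-empty")
    X = list(pos_seqs) + list(neg_seqs)
    y = [1] * len(pos_seqs) + [-1] * len(neg_seqs)
    model = NucleosomeOccupancyModel(k_max=k_max, C=C,
                                     strand_symmetric=strand_symmetric)
    return model.fit(X, y, seed=seed)


def score_sliding(seq: str, model: NucleosomeOccupancyModel) -> ScoreTrack:
    """Module-level convenience wrapper over :meth:`NucleosomeOccupancyModel.score_sliding`."""
    return model.score_sliding(seq)


def signal_to_scoretrack(track: SignalTrack, chrom: str, start: int, end: int,
                         strand: str = "+",
                         offsets: np.ndarray | None = None) -> ScoreTrack:
    """Copy a per-base signal over [start, end) into a boundary-relative ScoreTrack.

    For minus-strand regions the values are reversed so the axis runs
    transcript 5'->3'; missing data (NaN) is masked.  A region wholly
    outside coverage yields an all-masked track, not an error.
    """
    values = track.get(chrom, start, end)
    if strand == "-":
        values = values[::-1].copy()
    mask = np.isfinite(values)
    if offsets is None:
        offsets = np.arange(end - start)
    return ScoreTrack(offsets=np.asarray(offsets), values=values, mask=mask)
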