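"""Phosphorylation-propensity scoring.

Every unobserved phospho-acceptor receives a 0-1 propensity from the
kinase-specificity profile of its sequence window; acceptors with an MS
observation are pinned to exactly 1. Features are sums of position-specific
scoring-matrix (PSSM) weights over the 11-mer window, one feature per motif
in a 40-motif bank spanning proline-directed, basophilic, acidophilic and
tyrosine-kinase archetypes. A linear maximum-margin classifier is fit per
species and acceptor class (S/T pooled, Y separate) by deterministic
full-batch subgradient descent on the regularized hinge loss, and margins
are mapped to [0, 1] by a two-parameter logistic calibration fitted on the
training margins.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression

from .constants import AA_INDEX, AMINO_ACIDS, DEFAULT_FLANK, acceptor_class
from .conservation import SiteWindow, extract_window
from .integrate import NonRedundantProteome, SiteCatalog, acceptor_positions

DEFAULT_N_SAMPLES = {"ST": 2000, "Y": 800}
DEFAULT_HYPERPARAMS = {"lambda": 1e-3, "n_iter": 500}


@dataclass
class KinaseMotifPSSM:
    """Log-odds weights, (2*flank+1) positions x 20 residues."""

    kinase: str
    acceptor_class: str  # "ST" or "Y"
    weights: np.ndarray  # shape (2*flank+1, 20)
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (2 * self.flank + 1, len(AMINO_ACIDS)):
            raise ValueError(f"PSSM {self.kinase}: bad shape {self.weights.shape}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError(f"PSSM {self.kinase}: non-finite weights")


def load_pssm_bank(path=None) -> list:
    """Read a sparse PSSM bank TSV (kinase, acceptor_class, offset, residue,
    weight); absent cells are zero. ``path=None`` loads the bank shipped
    with the package."""
    if path is None:
        ref = resources.files("phosite_evo").joinpath("data/pssm_bank.tsv")
        with resources.as_file(ref) as p:
            return load_pssm_bank(p)
    cells: dict = {}
    order: list = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = (row["kinase"], row["acceptor_class"])
            if key not in cells:
                cells[key] = []
                order.append(key)
            cells[key].append((int(row["offset"]), row["residue"],
                               float(row["weight"])))
    bank = []
    for kinase, cls in order:
        w = np.zeros((2 * DEFAULT_FLANK + 1, len(AMINO_ACIDS)))
        for offset, residue, weight in cells[(kinase, cls)]:
            w[offset + DEFAULT_FLANK, AA_INDEX[residue]] = weight
        bank.append(KinaseMotifPSSM(kinase=kinase, acceptor_class=cls, weights=w))
    return bank


def write_pssm_bank(bank: Sequence[KinaseMotifPSSM], path) -> None:
    """Write only non-zero cells (sparse TSV)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["kinase", "acceptor_class", "offset", "residue", "weight"])
        for pssm in bank:
            for i in range(pssm.weights.shape[0]):
                for j in range(pssm.weights.shape[1]):
                    w = pssm.weights[i, j]
                    if w != 0.0:
                        writer.writerow([pssm.kinase, pssm.acceptor_class,
                                         i - pssm.flank, AMINO_ACIDS[j],
                                         repr(float(w))])


def default_bank() -> list:
    return load_pssm_bank(None)


def score_features(window: SiteWindow,
                   bank: Sequence[KinaseMotifPSSM]) -> np.ndarray:
    """One feature per motif: the sum of its PSSM weights over the window.

    Truncated positions (and residues outside the 20-letter alphabet, such
    as X) contribute weight 0. If every motif in the bank shares one
    acceptor class, the window center must be of that class.
    """
    classes = {p.acceptor_class for p in bank}
    center = window.center_residue
    if len(classes) == 1:
        want = classes.pop()
        if acceptor_class(center) != want:
            raise ValueError(
                f"window center {center!r} is not of acceptor class {want}")
    else:
        acceptor_class(center)  # raises unless S/T/Y
    flank = window.flank
    offsets, residues = [], []
    start = window.center_position - 1 - (0 if window.left_truncated
                                          else flank)
    # offset of the first residue of the clipped window relative to center
    first_offset = -(window.center_position - 1) if window.left_truncated else -flank
    for i, aa in enumerate(window.residues):
        idx = AA_INDEX.get(aa)
        if idx is not None:
            offsets.append(first_offset + i + flank)
            residues.append(idx)
    features = np.zeros(len(bank))
    if offsets:
        rows = np.asarray(offsets)
        cols = np.asarray(residues)
        for k, pssm in enumerate(bank):
            features[k] = pssm.weights[rows, cols].sum()
    return features


def feature_matrix(windows: Sequence[SiteWindow],
                   bank: Sequence[KinaseMotifPSSM]) -> np.ndarray:
    return np.array([score_features(w, bank) for w in windows])


def assemble_training_sets(catalog: SiteCatalog,
                           proteome: NonRedundantProteome,
                           acceptor_cls: str,
                           n_samples: Optional[int] = None,
                           seed: int = 0,
                           flank: int = DEFAULT_FLANK) -> tuple:
    """Sample detected sites (positives) and never-detected acceptors
    (negatives) of one acceptor class.

    Sampling is uniform without replacement, capped at availability, and
    reproducible from the seed. Negatives may contain real-but-undetected
    sites; no correction is applied. Returns two lists of SiteWindows.
    """
    if n_samples is None:
        n_samples = DEFAULT_N_SAMPLES[acceptor_cls]
    letters = {"ST": ("S", "T"), "Y": ("Y",)}[acceptor_cls]
    species = proteome.species
    detected = set()
    for rec in catalog.subset(species=species, ptm_type="phospho",
                              include_ambiguous=False):
        if rec.residue in letters:
            detected.add((rec.protein_id, rec.position))
    all_acceptors = []
    for pid in sorted(proteome.sequences):
        seq = proteome.sequences[pid]
        for pos in acceptor_positions(seq, frozenset(letters)):
            all_acceptors.append((pid, pos))
    negatives_pool = [a for a in all_acceptors if a not in detected]
    positives_pool = sorted(detected & set(all_acceptors))
    if not positives_pool or not negatives_pool:
        raise ValueError(
            f"cannot assemble {acceptor_cls} training set: "
            f"{len(positives_pool)} positives, {len(negatives_pool)} negatives")
    rng = np.random.default_rng(seed)

    def sample(pool):
        take = min(n_samples, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        return [pool[i] for i in sorted(idx)]

    def windows(pairs):
        return [extract_window(proteome.sequences[pid], pos, flank)
                for pid, pos in pairs]

    return windows(sample(positives_pool)), windows(sample(sorted(negatives_pool)))


@dataclass
class PropensityModel:
    """Linear margin classifier with logistic calibration to [0, 1]."""

    species: str
    acceptor_class: str
    weights: np.ndarray  # one per motif in the bank
    bias: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    calib_slope: float
    calib_intercept: float
    metadata: dict = field(default_factory=dict)

    def margin(self, features: np.ndarray) -> np.ndarray:
        X = (np.atleast_2d(features) - self.feature_mean) / self.feature_scale
        return X @ self.weights + self.bias

    def calibrate(self, margins: np.ndarray) -> np.ndarray:
        z = self.calib_slope * margins + self.calib_intercept
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self, path) -> None:
        payload = {
            "format_version": 1,
            "species": self.species,
            "acceptor_class": self.acceptor_class,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "calib_slope": self.calib_slope,
            "calib_intercept": self.calib_intercept,
            "metadata": self.metadata,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PropensityModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if d.get("format_version") != 1:
            raise ValueError(f"unsupported model format {d.get('format_version')}")
        return cls(species=d["species"], acceptor_class=d["acceptor_class"],
                   weights=np.asarray(d["weights"]), bias=d["bias"],
                   feature_mean=np.asarray(d["feature_mean"]),
                   feature_scale=np.asarray(d["feature_scale"]),
                   calib_slope=d["calib_slope"],
                   calib_intercept=d["calib_intercept"],
                   metadata=d.get("metadata", {}))


def _subgradient_hinge(X: np.ndarray, y: np.ndarray, lam: float,
                       n_iter: int) -> tuple:
    """Full-batch subgradient descent on (lam/2)||w||^2 + mean hinge loss.

    Step size 1/(lam * t); the bias is unregularized. Deterministic: zero
    initialization, fixed iteration count, no shuffling.
    """
    n, d = X.shape
    w = np.zeros(d)
    b = 0.0
    for t in range(1, n_iter + 1):
        eta = 1.0 / (lam * t)
        margins = y * (X @ w + b)
        active = margins < 1.0
        if active.any():
            grad_w = lam * w - (y[active, None] * X[active]).sum(axis=0) / n
            grad_b = -y[active].sum() / n
        else:
            grad_w = lam * w
            grad_b = 0.0
        w -= eta * grad_w
        b -= eta * grad_b
    return w, b


def train_propensity_model(positives: Sequence[SiteWindow],
                           negatives: Sequence[SiteWindow],
                           bank: Sequence[KinaseMotifPSSM],
                           species: str = "",
                           hyperparams: Optional[dict] = None,
                           seed: int = 0) -> PropensityModel:
    """Fit the margin classifier and its calibration on labelled windows.

    Features are standardized on the training set. Identical feature
    populations across the two classes (all-constant features) raise an
    error since no separating direction exists.
    """
    if not positives or not negatives:
        raise ValueError("both classes must be non-empty")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    cls = acceptor_class(positives[0].center_residue)
    X = feature_matrix(list(positives) + list(negatives), bank)
    y = np.concatenate([np.ones(len(positives)), -np.ones(len(negatives))])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    if np.all(scale == 0.0):
        raise ValueError("degenerate training set: all features constant "
                         "across both classes (non-separable)")
    scale = np.where(scale == 0.0, 1.0, scale)
    Xs = (X - mean) / scale
    w, b = _subgradient_hinge(Xs, y, hp["lambda"], hp["n_iter"])
    margins = Xs @ w + b
    # Platt scaling of the margin; high C approximates unpenalized fit
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(margins.reshape(-1, 1), (y > 0).astype(int))
    return PropensityModel(
        species=species, acceptor_class=cls, weights=w, bias=b,
        feature_mean=mean, feature_scale=scale,
        calib_slope=float(lr.coef_[0, 0]),
        calib_intercept=float(lr.intercept_[0]),
        metadata={"n_positives": len(positives), "n_negatives": len(negatives),
                  "seed": seed, "hyperparams": hp, "bank_size": len(bank)})


def predict_propensity(model: PropensityModel, window: SiteWindow,
                       bank: Sequence[KinaseMotifPSSM],
                       observed: bool = False) -> float:
    """Calibrated 0-1 propensity; MS-observed sites always score exactly 1."""
    if observed:
        return 1.0
    if acceptor_class(window.center_residue) != model.acceptor_class:
        raise ValueError("window acceptor class does not match model")
    features = score_features(window, bank)
    return float(model.calibrate(model.margin(features))[0])
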