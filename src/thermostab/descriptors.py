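"""Sequence-derived protein descriptors.

Implements the full feature battery used for melting-temperature
regression: amino-acid and dipeptide composition, windowed dipeptide
counts over a 21-symbol alphabet, six-group counts/frequencies, CTD
(composition/transition/distribution over the seven classical three-class
property partitions), Moreau–Broto/Moran/Geary autocorrelation,
sequence-order coupling numbers and quasi-sequence-order descriptors
(Grantham and physicochemical distance matrices), pseudo and amphiphilic
pseudo amino-acid composition, conjoint triads, and a 28-feature
physicochemical block.

Every family is registered with a fixed name, a length precondition and a
stable, namespaced feature-name list; :func:`featurize` concatenates the
enabled families in a fixed documented order into a :class:`FeatureMatrix`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FeatureError
from .physchem import PHYSCHEM_NAMES, physchem_block
from .sequence_io import ProteinRecord
from .tables import (
    AA_GROUPS_6,
    CTD_PROPERTIES,
    DEFAULT_AUTOCORR_SCALES,
    HOPP_WOODS,
    KYTE_DOOLITTLE,
    OTHER_SYMBOL,
    SIDE_CHAIN_MASS,
    STANDARD_AA,
    TRIAD_CLASSES,
    grantham_matrix,
    standardize_scale,
)

logger = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}
_EXTENDED_AA = STANDARD_AA + OTHER_SYMBOL  # 21-symbol alphabet


# ---------------------------------------------------------------------------
# Configuration and feature matrix containers
# ---------------------------------------------------------------------------

#: Fixed assembly order of the descriptor families.
FAMILY_ORDER: tuple[str, ...] = (
    "aac", "dpc", "windip", "grp", "ctd", "autocorr",
    "socn", "qso", "paac", "apaac", "triad", "physchem",
)


@dataclass
class DescriptorConfig:
    """Tunable descriptor parameters.

    Defaults follow the established conventions of the protein descriptor
    literature: lag/lambda 30 for the sequence-order families, PAAC weight
    0.05, QSO weight 0.1, window 21 for the windowed dipeptide counts.
    """

    nlag_autocorr: int = 30
    nlag_socn: int = 30
    paac_lambda: int = 30
    paac_weight: float = 0.05
    qso_weight: float = 0.1
    window: int = 21
    group_map: dict[str, str] = field(default_factory=lambda: dict(AA_GROUPS_6))
    enabled_families: tuple[str, ...] = FAMILY_ORDER
    autocorr_scales: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AUTOCORR_SCALES.items()}
    )

    def __post_init__(self) -> None:
        for name in ("nlag_autocorr", "nlag_socn", "paac_lambda"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.paac_weight < 1:
            raise ValueError("paac_weight must be in (0, 1)")
        if not 0 < self.qso_weight < 1:
            raise ValueError("qso_weight must be in (0, 1)")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        joined = "".join(self.group_map.values())
        if sorted(joined) != sorted(STANDARD_AA):
            raise ValueError(
                "group_map must partition the 20 standard amino acids exactly"
            )
        unknown = set(self.enabled_families) - set(FAMILY_ORDER)
        if unknown:
            raise ValueError(f"unknown descriptor families: {sorted(unknown)}")

    @property
    def min_sequence_length(self) -> int:
        """Weakest length making every enabled family well-defined."""
        return max(
            _FAMILIES[f].min_length(self) for f in self.enabled_families
        )

    def to_dict(self) -> dict:
        return {
            "nlag_autocorr": self.nlag_autocorr,
            "nlag_socn": self.nlag_socn,
            "paac_lambda": self.paac_lambda,
            "paac_weight": self.paac_weight,
            "qso_weight": self.qso_weight,
            "window": self.window,
            "group_map": self.group_map,
            "enabled_families": list(self.enabled_families),
            "autocorr_scales": self.autocorr_scales,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorConfig":
        d = dict(d)
        if "enabled_families" in d:
            d["enabled_families"] = tuple(d["enabled_families"])
        return cls(**d)

    def fingerprint(self) -> str:
        """Stable hash of the configuration (provenance check at predict time)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FeatureMatrix:
    """Named, ordered feature vectors for a set of records."""

    record_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # shape (n_records, n_features)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.record_ids), len(self.feature_names)):
            raise FeatureError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.record_ids)} records x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise FeatureError("feature names must be unique")

    @property
    def n_records(self) -> int:
        return len(self.record_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the requested order; missing names are an error."""
        index = {n: j for j, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise FeatureError(f"missing feature columns: {missing[:10]}")
        cols = [index[n] for n in names]
        return FeatureMatrix(list(self.record_ids), list(names), self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.record_ids, name="id"),
            columns=self.feature_names,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        return cls(
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            frame.to_numpy(dtype=float),
        )

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col="id"))


# ---------------------------------------------------------------------------
# Composition families
# ---------------------------------------------------------------------------

def aa_composition(seq: str) -> np.ndarray:
    """Frequencies of the 20 standard residues (sums to 1)."""
    if not seq:
        raise FeatureError("aa_composition requires length >= 1")
    out = np.zeros(20)
    for a in seq:
        out[_AA_INDEX[a]] += 1.0
    return out / len(seq)


def dipeptide_composition(seq: str) -> np.ndarray:
    """Frequencies of the 400 ordered residue pairs among adjacent pairs."""
    if len(seq) < 2:
        raise FeatureError("dipeptide_composition requires length >= 2")
    out = np.zeros(400)
    for i in range(len(seq) - 1):
        out[_AA_INDEX[seq[i]] * 20 + _AA_INDEX[seq[i + 1]]] += 1.0
    return out / (len(seq) - 1)


def windowed_dipeptide_counts(seq: str, window: int = 21) -> np.ndarray:
    """441 dipeptide counts accumulated over sliding windows.

    Windows are ``seq[j:j+window]`` for every start ``j`` with at least two
    residues remaining (stride 1; terminal windows truncate at the right
    end). The alphabet has 21 symbols: the 20 standard residues plus one
    reserved placeholder, so the output length is 21^2 = 441. An adjacent
    pair starting at position ``i`` is contained in ``min(i+1, window-1)``
    windows; counts are accumulated with that multiplicity.
    """
    if window < 2:
        raise FeatureError("window must be >= 2")
    if len(seq) < 2:
        raise FeatureError("windowed_dipeptide_counts requires length >= 2")
    idx = {a: i for i, a in enumerate(_EXTENDED_AA)}
    out = np.zeros(441)
    for i in range(len(seq) - 1):
        mult = min(i + 1, window - 1)
        out[idx[seq[i]] * 21 + idx[seq[i + 1]]] += mult
    return out


def aa_group_features(seq: str, group_map: dict[str, str] | None = None) -> np.ndarray:
    """Counts and frequencies of the six physicochemical groups (12 values)."""
    if not seq:
        raise FeatureError("aa_group_features requires length >= 1")
    group_map = group_map or AA_GROUPS_6
    counts = np.array(
        [sum(seq.count(a) for a in letters) for letters in group_map.values()],
        dtype=float,
    )
    return np.concatenate([counts, counts / len(seq)])


def conjoint_triad(seq: str) -> np.ndarray:
    """Counts of consecutive triples over the seven-class grouping (343 values)."""
    if len(seq) < 3:
        raise FeatureError("conjoint_triad requires length >= 3")
    cls = {a: c for c, letters in enumerate(TRIAD_CLASSES) for a in letters}
    out = np.zeros(343)
    for i in range(len(seq) - 2):
        out[cls[seq[i]] * 49 + cls[seq[i + 1]] * 7 + cls[seq[i + 2]]] += 1.0
    return out


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

def ctd_features(seq: str) -> np.ndarray:
    """Composition/Transition/Distribution over the 7 property partitions.

    Per property: 3 class fractions, 3 transition frequencies (unordered
    class pairs among adjacent residues, normalized by L-1) and 15
    distribution values — for each class the position (percent of sequence
    length, 1-based) of its first, 25%, 50%, 75% and last occurrence;
    all five are 0 when the class is absent. 7 x 21 = 147 values.
    """
    if len(seq) < 2:
        raise FeatureError("ctd_features requires length >= 2")
    L = len(seq)
    out: list[float] = []
    for prop, classes in CTD_PROPERTIES.items():
        cls_of = {a: k for k, letters in enumerate(classes) for a in letters}
        labels = [cls_of[a] for a in seq]
        # composition
        comp = [labels.count(k) / L for k in range(3)]
        out.extend(comp)
        # transitions: unordered pairs (0,1), (0,2), (1,2)
        trans = [0, 0, 0]
        pair_index = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        for i in range(L - 1):
            a, b = labels[i], labels[i + 1]
            if a != b:
                trans[pair_index[(min(a, b), max(a, b))]] += 1
        out.extend(t / (L - 1) for t in trans)
        # distribution
        for k in range(3):
            positions = [i + 1 for i, c in enumerate(labels) if c == k]
            if not positions:
                out.extend([0.0] * 5)
                continue
            nk = len(positions)
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                rank = 1 if frac == 0.0 else max(1, math.ceil(frac * nk))
                out.append(positions[rank - 1] / L * 100.0)
    return np.array(out)


def _ctd_names() -> list[str]:
    names = []
    for prop in CTD_PROPERTIES:
        names += [f"ctd.{prop}.comp.g{k}" for k in (1, 2, 3)]
        names += [f"ctd.{prop}.trans.{p}" for p in ("g1g2", "g1g3", "g2g3")]
        for k in (1, 2, 3):
            names += [
                f"ctd.{prop}.dist.g{k}.{p}"
                for p in ("first", "p25", "p50", "p75", "p100")
            ]
    return names


# ---------------------------------------------------------------------------
# Autocorrelation
# ---------------------------------------------------------------------------

def autocorrelation(
    seq: str,
    scales: dict[str, dict[str, float]] | None = None,
    nlag: int = 30,
    kind: Literal["moreau_broto", "moran", "geary"] = "moreau_broto",
) -> np.ndarray:
    """Sequence autocorrelation of per-residue scales at lags 1..nlag.

    Scales are standardized to mean 0 / SD 1 over the 20 residues before
    use. ``moreau_broto`` is the normalized form (1/(L-d)) * sum p_i p_{i+d};
    Moran and Geary follow their classical formulas with the sequence mean
    and variance of the scale values. A scale that is constant over the
    sequence leaves Moran/Geary undefined (0/0); the convention is 0 with
    a logged warning. Output is scale-major then lag.
    """
    scales = scales or DEFAULT_AUTOCORR_SCALES
    L = len(seq)
    if L <= nlag:
        raise FeatureError(f"autocorrelation requires length > nlag ({nlag})")
    out = []
    for sname, scale in scales.items():
        std = standardize_scale(scale)
        p = np.array([std[a] for a in seq])
        pbar = p.mean()
        centered = p - pbar
        var_seq = float(np.dot(centered, centered))
        # a constant scale vector leaves Moran/Geary undefined (0/0); test
        # the raw values, not the centered sum, to dodge rounding in pbar
        degenerate = bool(np.all(p == p[0]))
        if degenerate and kind in ("moran", "geary"):
            logger.warning(
                "zero-variance scale %r on sequence; %s set to 0", sname, kind
            )
        for d in range(1, nlag + 1):
            a, b = p[:-d], p[d:]
            if kind == "moreau_broto":
                out.append(float(np.dot(a, b)) / (L - d))
            elif kind == "moran":
                if degenerate:
                    out.append(0.0)
                else:
                    num = float(np.dot(centered[:-d], centered[d:])) / (L - d)
                    out.append(num / (var_seq / L))
            else:  # geary
                if degenerate:
                    out.append(0.0)
                else:
                    num = float(np.sum((a - b) ** 2)) / (2 * (L - d))
                    out.append(num / (var_seq / (L - 1)))
    return np.array(out)


# ---------------------------------------------------------------------------
# Sequence-order descriptors (SOCN / QSO)
# ---------------------------------------------------------------------------

def _physchem_distance_sq() -> np.ndarray:
    """Squared physicochemical distance over the classical PAAC scale triplet
    (standardized hydrophobicity, hydrophilicity, side-chain mass), i.e.
    d2(a,b) = mean of squared scale differences, normalized to max 1."""
    mats = []
    for scale in (KYTE_DOOLITTLE, HOPP_WOODS, SIDE_CHAIN_MASS):
        std = standardize_scale(scale)
        v = np.array([std[a] for a in STANDARD_AA])
        mats.append((v[:, None] - v[None, :]) ** 2)
    d2 = np.mean(mats, axis=0)
    return d2 / d2.max()


def _grantham_distance_sq() -> np.ndarray:
    g = grantham_matrix()
    g = g / g.max()
    return g ** 2


_DISTANCE_MATRICES: dict[str, Callable[[], np.ndarray]] = {
    "pcd": _physchem_distance_sq,
    "grantham": _grantham_distance_sq,
}
_D2_CACHE: dict[str, np.ndarray] = {}


def _d2(matrix: str) -> np.ndarray:
    if matrix not in _D2_CACHE:
        _D2_CACHE[matrix] = _DISTANCE_MATRICES[matrix]()
    return _D2_CACHE[matrix]


def sequence_order_coupling(
    seq: str, nlag: int = 30, matrix: str = "pcd"
) -> np.ndarray:
    """Sequence-order coupling numbers tau_d = sum_i d2(p_i, p_{i+d}), d=1..nlag."""
    L = len(seq)
    if L <= nlag:
        raise FeatureError(f"sequence_order_coupling requires length > nlag ({nlag})")
    d2 = _d2(matrix)
    codes = np.array([_AA_INDEX[a] for a in seq])
    return np.array(
        [float(d2[codes[:-d], codes[d:]].sum()) for d in range(1, nlag + 1)]
    )


def quasi_sequence_order(
    seq: str, nlag: int = 30, weight: float = 0.1, matrix: str = "pcd"
) -> np.ndarray:
    """Quasi-sequence-order descriptors: 20 composition terms + nlag coupling
    terms mixed with ``weight``; the block sums to 1 by construction."""
    f = aa_composition(seq)
    tau = sequence_order_coupling(seq, nlag, matrix)
    denom = 1.0 + weight * tau.sum()
    return np.concatenate([f / denom, weight * tau / denom])


def sequence_order_features(
    seq: str, nlag: int = 30, weight: float = 0.1
) -> np.ndarray:
    """SOCN + QSO under both distance matrices (2*nlag + 2*(20+nlag) values)."""
    return np.concatenate(
        [
            sequence_order_coupling(seq, nlag, "pcd"),
            sequence_order_coupling(seq, nlag, "grantham"),
            quasi_sequence_order(seq, nlag, weight, "pcd"),
            quasi_sequence_order(seq, nlag, weight, "grantham"),
        ]
    )


# ---------------------------------------------------------------------------
# PAAC / APAAC
# ---------------------------------------------------------------------------

_PAAC_SCALES = (KYTE_DOOLITTLE, HOPP_WOODS, SIDE_CHAIN_MASS)


def _paac_theta(seq: str, lam: int) -> np.ndarray:
    """Correlation factors theta_k, k=1..lam (mean over the scale triplet)."""
    stds = [standardize_scale(s) for s in _PAAC_SCALES]
    ps = [np.array([std[a] for a in seq]) for std in stds]
    thetas = []
    for k in range(1, lam + 1):
        acc = np.zeros(len(seq) - k)
        for p in ps:
            acc += (p[:-k] - p[k:]) ** 2
        thetas.append(float(acc.mean()) / len(ps))
    return np.array(thetas)


def paac(seq: str, lam: int = 30, weight: float = 0.05) -> np.ndarray:
    """Pseudo amino-acid composition: 20 + lam values summing to 1."""
    if len(seq) <= lam:
        raise FeatureError(f"paac requires length > lambda ({lam})")
    f = aa_composition(seq)
    theta = _paac_theta(seq, lam)
    denom = 1.0 + weight * theta.sum()
    return np.concatenate([f / denom, weight * theta / denom])


def apaac(seq: str, lam: int = 30, weight: float = 0.05) -> np.ndarray:
    """Amphiphilic PAAC: 20 + 2*lam values summing to 1.

    Correlation terms pair hydrophobicity and hydrophilicity products at
    each lag (tau ordered h1, h2 within each lag).
    """
    if len(seq) <= lam:
        raise FeatureError(f"apaac requires length > lambda ({lam})")
    f = aa_composition(seq)
    h1 = standardize_scale(KYTE_DOOLITTLE)
    h2 = standardize_scale(HOPP_WOODS)
    p1 = np.array([h1[a] for a in seq])
    p2 = np.array([h2[a] for a in seq])
    taus = []
    for k in range(1, lam + 1):
        taus.append(float((p1[:-k] * p1[k:]).mean()))
        taus.append(float((p2[:-k] * p2[k:]).mean()))
    taus = np.array(taus)
    denom = 1.0 + weight * taus.sum()
    return np.concatenate([f / denom, weight * taus / denom])


def paac_apaac(seq: str, lam: int = 30, weight: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Convenience pair (PAAC, APAAC)."""
    return paac(seq, lam, weight), apaac(seq, lam, weight)


# ---------------------------------------------------------------------------
# Family registry and featurize
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Family:
    name: str
    min_length: Callable[[DescriptorConfig], int]
    names: Callable[[DescriptorConfig], list[str]]
    compute: Callable[[str, DescriptorConfig], np.ndarray]


def _autocorr_names(cfg: DescriptorConfig) -> list[str]:
    return [
        f"ac.{kind}.{scale}.lag{d}"
        for kind in ("moreau_broto", "moran", "geary")
        for scale in cfg.autocorr_scales
        for d in range(1, cfg.nlag_autocorr + 1)
    ]


def _autocorr_all(seq: str, cfg: DescriptorConfig) -> np.ndarray:
    return np.concatenate(
        [
            autocorrelation(seq, cfg.autocorr_scales, cfg.nlag_autocorr, kind)
            for kind in ("moreau_broto", "moran", "geary")
        ]
    )


_FAMILIES: dict[str, _Family] = {
    "aac": _Family(
        "aac", lambda c: 1,
        lambda c: [f"aac.{a}" for a in STANDARD_AA],
        lambda s, c: aa_composition(s),
    ),
    "dpc": _Family(
        "dpc", lambda c: 2,
        lambda c: [f"dpc.{a}{b}" for a in STANDARD_AA for b in STANDARD_AA],
        lambda s, c: dipeptide_composition(s),
    ),
    "windip": _Family(
        "windip", lambda c: 2,
        lambda c: [f"windip.{a}{b}" for a in _EXTENDED_AA for b in _EXTENDED_AA],
        lambda s, c: windowed_dipeptide_counts(s, c.window),
    ),
    "grp": _Family(
        "grp", lambda c: 1,
        lambda c: [f"grp.count_{g}" for g in c.group_map]
        + [f"grp.freq_{g}" for g in c.group_map],
        lambda s, c: aa_group_features(s, c.group_map),
    ),
    "ctd": _Family(
        "ctd", lambda c: 2, lambda c: _ctd_names(), lambda s, c: ctd_features(s)
    ),
    "autocorr": _Family(
        "autocorr", lambda c: c.nlag_autocorr + 1, _autocorr_names, _autocorr_all
    ),
    "socn": _Family(
        "socn", lambda c: c.nlag_socn + 1,
        lambda c: [
            f"socn.{m}.d{d}" for m in ("pcd", "grantham")
            for d in range(1, c.nlag_socn + 1)
        ],
        lambda s, c: np.concatenate(
            [
                sequence_order_coupling(s, c.nlag_socn, "pcd"),
                sequence_order_coupling(s, c.nlag_socn, "grantham"),
            ]
        ),
    ),
    "qso": _Family(
        "qso", lambda c: c.nlag_socn + 1,
        lambda c: [
            f"qso.{m}.{t}" for m in ("pcd", "grantham")
            for t in list(STANDARD_AA) + [f"tau{d}" for d in range(1, c.nlag_socn + 1)]
        ],
        lambda s, c: np.concatenate(
            [
                quasi_sequence_order(s, c.nlag_socn, c.qso_weight, "pcd"),
                quasi_sequence_order(s, c.nlag_socn, c.qso_weight, "grantham"),
            ]
        ),
    ),
    "paac": _Family(
        "paac", lambda c: c.paac_lambda + 1,
        lambda c: [f"paac.{a}" for a in STANDARD_AA]
        + [f"paac.lam{k}" for k in range(1, c.paac_lambda + 1)],
        lambda s, c: paac(s, c.paac_lambda, c.paac_weight),
    ),
    "apaac": _Family(
        "apaac", lambda c: c.paac_lambda + 1,
        lambda c: [f"apaac.{a}" for a in STANDARD_AA]
        + [
            f"apaac.{h}.lam{k}"
            for k in range(1, c.paac_lambda + 1)
            for h in ("h1", "h2")
        ],
        lambda s, c: apaac(s, c.paac_lambda, c.paac_weight),
    ),
    "triad": _Family(
        "triad", lambda c: 3,
        lambda c: [
            f"triad.{i}{j}{k}"
            for i in range(1, 8) for j in range(1, 8) for k in range(1, 8)
        ],
        lambda s, c: conjoint_triad(s),
    ),
    "physchem": _Family(
        "physchem", lambda c: 1,
        lambda c: [f"pp.{n}" for n in PHYSCHEM_NAMES],
        lambda s, c: physchem_block(s),
    ),
}


def feature_names(config: DescriptorConfig | None = None) -> list[str]:
    """Ordered feature names of the enabled families."""
    config = config or DescriptorConfig()
    names: list[str] = []
    for fam in FAMILY_ORDER:
        if fam in config.enabled_families:
            names.extend(_FAMILIES[fam].names(config))
    return names


def feature_dictionary(config: DescriptorConfig | None = None) -> pd.DataFrame:
    """Machine-readable dictionary: feature name -> family, block position."""
    config = config or DescriptorConfig()
    rows = []
    for fam in FAMILY_ORDER:
        if fam in config.enabled_families:
            for pos, name in enumerate(_FAMILIES[fam].names(config)):
                rows.append({"feature": name, "family": fam, "position": pos})
    return pd.DataFrame(rows)


def featurize(
    records: Iterable[ProteinRecord],
    config: DescriptorConfig | None = None,
    on_invalid: Literal["raise", "drop"] = "raise",
) -> FeatureMatrix:
    """Assemble the enabled descriptor families into a FeatureMatrix.

    Records violating a family length precondition raise
    :class:`FeatureError` naming the record and family, or are silently
    excluded under ``on_invalid="drop"``. Rows follow the input record
    order; columns are deterministic for a fixed config.
    """
    config = config or DescriptorConfig()
    fams = [_FAMILIES[f] for f in FAMILY_ORDER if f in config.enabled_families]
    if not fams:
        raise FeatureError("no descriptor families enabled")
    names = feature_names(config)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in records:
        L = len(rec.sequence)
        short = [f.name for f in fams if L < f.min_length(config)]
        if short:
            if on_invalid == "drop":
                logger.warning(
                    "record %s (length %d) dropped: too short for %s",
                    rec.id, L, short,
                )
                continue
            raise FeatureError(
                f"record {rec.id!r} (length {L}) is too short for "
                f"families {short}"
            )
        row = np.concatenate([f.compute(rec.sequence, config) for f in fams])
        if not np.all(np.isfinite(row)):
            bad = [names[j] for j in np.flatnonzero(~np.isfinite(row))[:5]]
            raise FeatureError(f"non-finite features for record {rec.id!r}: {bad}")
        ids.append(rec.id)
        rows.append(row)
    values = np.vstack(rows) if rows else np.empty((0, len(names)))
    return FeatureMatrix(ids, names, values)
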