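"""Independent brute-force oracles for descriptor and metric definitions.

Every function here is written directly from the published definition of
the descriptor, using plain Python loops and its own standardization code,
sharing only the constant reference tables with the implementation.
"""

from __future__ import annotations

import math

from thermostab.tables import (
    AA_GROUPS_6,
    CTD_PROPERTIES,
    HOPP_WOODS,
    KYTE_DOOLITTLE,
    OTHER_SYMBOL,
    SIDE_CHAIN_MASS,
    STANDARD_AA,
    TRIAD_CLASSES,
    grantham_matrix,
)

AA = STANDARD_AA
EXT = STANDARD_AA + OTHER_SYMBOL


def _standardize(scale: dict) -> dict:
    vals = [scale[a] for a in AA]
    mu = sum(vals) / 20
    sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / 20)
    return {a: (scale[a] - mu) / sd for a in AA}


def oracle_aac(seq: str) -> list[float]:
    return [seq.count(a) / len(seq) for a in AA]


def oracle_dpc(seq: str) -> list[float]:
    pairs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    return [pairs.count(a + b) / len(pairs) for a in AA for b in AA]


def oracle_windip(seq: str, window: int = 21) -> list[float]:
    """Explicit enumeration of every sliding window and its adjacent pairs."""
    counts = {a + b: 0 for a in EXT for b in EXT}
    for j in range(len(seq) - 1):  # every start with >= 2 residues left
        win = seq[j : j + window]
        for i in range(len(win) - 1):
            counts[win[i : i + 2]] += 1
    return [float(counts[a + b]) for a in EXT for b in EXT]


def oracle_groups(seq: str) -> list[float]:
    counts = [
        sum(1 for c in seq if c in letters) for letters in AA_GROUPS_6.values()
    ]
    return [float(c) for c in counts] + [c / len(seq) for c in counts]


def oracle_ctd(seq: str) -> list[float]:
    L = len(seq)
    out: list[float] = []
    for classes in CTD_PROPERTIES.values():
        labels = []
        for c in seq:
            for k, letters in enumerate(classes):
                if c in letters:
                    labels.append(k)
                    break
        for k in range(3):
            out.append(labels.count(k) / L)
        for pair in ((0, 1), (0, 2), (1, 2)):
            t = 0
            for i in range(L - 1):
                if (labels[i], labels[i + 1]) in (pair, pair[::-1]):
                    t += 1
            out.append(t / (L - 1))
        for k in range(3):
            pos = [i + 1 for i in range(L) if labels[i] == k]
            if not pos:
                out.extend([0.0] * 5)
                continue
            out.append(pos[0] / L * 100)
            for frac in (0.25, 0.5, 0.75, 1.0):
                out.append(pos[max(1, math.ceil(frac * len(pos))) - 1] / L * 100)
    return out


def oracle_autocorr(seq: str, scale: dict, nlag: int, kind: str) -> list[float]:
    std = _standardize(scale)
    p = [std[c] for c in seq]
    L = len(p)
    pbar = sum(p) / L
    out = []
    for d in range(1, nlag + 1):
        if kind == "moreau_broto":
            out.append(sum(p[i] * p[i + d] for i in range(L - d)) / (L - d))
        elif kind == "moran":
            den = sum((x - pbar) ** 2 for x in p) / L
            if den == 0:
                out.append(0.0)
                continue
            num = sum((p[i] - pbar) * (p[i + d] - pbar) for i in range(L - d)) / (L - d)
            out.append(num / den)
        elif kind == "geary":
            den = sum((x - pbar) ** 2 for x in p) / (L - 1)
            if den == 0:
                out.append(0.0)
                continue
            num = sum((p[i] - p[i + d]) ** 2 for i in range(L - d)) / (2 * (L - d))
            out.append(num / den)
    return out


def _oracle_d2(matrix: str) -> dict:
    if matrix == "grantham":
        g = grantham_matrix()
        gmax = max(max(row) for row in g.tolist())
        return {
            (a, b): (g[i][j] / gmax) ** 2
            for i, a in enumerate(AA)
            for j, b in enumerate(AA)
        }
    # physicochemical triplet distance
    stds = [_standardize(s) for s in (KYTE_DOOLITTLE, HOPP_WOODS, SIDE_CHAIN_MASS)]
    d2 = {
        (a, b): sum((s[a] - s[b]) ** 2 for s in stds) / 3
        for a in AA
        for b in AA
    }
    m = max(d2.values())
    return {k: v / m for k, v in d2.items()}


def oracle_socn(seq: str, nlag: int, matrix: str) -> list[float]:
    d2 = _oracle_d2(matrix)
    L = len(seq)
    return [
        sum(d2[(seq[i], seq[i + d])] for i in range(L - d)) for d in range(1, nlag + 1)
    ]


def oracle_qso(seq: str, nlag: int, weight: float, matrix: str) -> list[float]:
    f = oracle_aac(seq)
    tau = oracle_socn(seq, nlag, matrix)
    denom = 1.0 + weight * sum(tau)
    return [x / denom for x in f] + [weight * t / denom for t in tau]


def oracle_paac(seq: str, lam: int, weight: float) -> list[float]:
    stds = [_standardize(s) for s in (KYTE_DOOLITTLE, HOPP_WOODS, SIDE_CHAIN_MASS)]
    L = len(seq)
    thetas = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - k):
            total += sum((s[seq[i]] - s[seq[i + k]]) ** 2 for s in stds) / 3
        thetas.append(total / (L - k))
    f = oracle_aac(seq)
    denom = 1.0 + weight * sum(thetas)
    return [x / denom for x in f] + [weight * t / denom for t in thetas]


def oracle_apaac(seq: str, lam: int, weight: float) -> list[float]:
    h1 = _standardize(KYTE_DOOLITTLE)
    h2 = _standardize(HOPP_WOODS)
    L = len(seq)
    taus = []
    for k in range(1, lam + 1):
        taus.append(sum(h1[seq[i]] * h1[seq[i + k]] for i in range(L - k)) / (L - k))
        taus.append(sum(h2[seq[i]] * h2[seq[i + k]] for i in range(L - k)) / (L - k))
    f = oracle_aac(seq)
    denom = 1.0 + weight * sum(taus)
    return [x / denom for x in f] + [weight * t / denom for t in taus]


def oracle_triad(seq: str) -> list[float]:
    cls = {a: c for c, letters in enumerate(TRIAD_CLASSES) for a in letters}
    counts = [0.0] * 343
    for i in range(len(seq) - 2):
        counts[cls[seq[i]] * 49 + cls[seq[i + 1]] * 7 + cls[seq[i + 2]]] += 1
    return counts


# -- metric oracles ---------------------------------------------------------

def oracle_pcc(y_pred, y_true) -> float:
    n = len(y_pred)
    mx = sum(y_pred) / n
    my = sum(y_true) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(y_pred, y_true)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in y_pred) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y_true) / n)
    return cov / (sx * sy)


def oracle_mse(y_pred, y_true) -> float:
    return sum((a - b) ** 2 for a, b in zip(y_pred, y_true)) / len(y_pred)


def oracle_rmse(y_pred, y_true) -> float:
    return math.sqrt(oracle_mse(y_pred, y_true))


def oracle_mae(y_pred, y_true) -> float:
    return sum(abs(a - b) for a, b in zip(y_pred, y_true)) / len(y_pred)


def oracle_r2(y_pred, y_true) -> float:
    my = sum(y_true) / len(y_true)
    ss_res = sum((a - b) ** 2 for a, b in zip(y_pred, y_true))
    ss_tot = sum((b - my) ** 2 for b in y_true)
    return 1.0 - ss_res / ss_tot
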