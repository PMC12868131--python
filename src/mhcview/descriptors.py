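"""Handcrafted amino-acid descriptor baselines.

Classic alignment-free encodings used as comparison features against
the learned embeddings: amino-acid composition (AAC), dipeptide
deviation from expected mean (DDE), composition of k-spaced amino-acid
pairs (CKSAAP), conjoint triad (CTriad), the composition / transition /
distribution family (CTDC, CTDT, CTDD), and quasi-sequence-order
(QSOrder).  Group tables follow the conventional seven physicochemical
property partitions; QSOrder couples residues through two
physicochemical distance matrices computed from standard published
scales (see ``_DISTANCE_MATRICES``).

Every descriptor is a pure, deterministic function of the sequence.
Nonstandard letters (B, J, O, U, Z) are mapped to X and X positions are
excluded from counts, with effective lengths reduced accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .data_io import AMINO_ACIDS

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_DIPEPTIDES = ["".join(p) for p in product(AMINO_ACIDS, repeat=2)]

#: sense-codon multiplicities of the standard genetic code (61 total)
_CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
    "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
    "T": 4, "V": 4, "W": 1, "Y": 2,
}

#: conjoint-triad classes (dipole/volume clustering of the 20 residues)
_TRIAD_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

#: seven-property CTD groupings, three classes per property
_CTD_GROUPS = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASCTPD", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}
_CTD_PROPERTIES = tuple(_CTD_GROUPS)

# residue scales for the QSOrder distance matrices
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}
_ISOELECTRIC = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
}


def _distance_matrix(scales: list[dict[str, float]]) -> np.ndarray:
    """Euclidean distance over z-scored residue property scales."""
    cols = []
    for scale in scales:
        v = np.array([scale[a] for a in AMINO_ACIDS])
        cols.append((v - v.mean()) / v.std())
    P = np.stack(cols, axis=1)
    diff = P[:, None, :] - P[None, :, :]
    return np.sqrt((diff**2).sum(-1))


#: two fixed matrices → QSOrder dimension 2*(20 + nlag)
_DISTANCE_MATRICES = (
    _distance_matrix([_KYTE_DOOLITTLE, _RESIDUE_MASS, _ISOELECTRIC]),
    _distance_matrix([_KYTE_DOOLITTLE]),
)

DESCRIPTOR_IDS = ("AAC", "DDE", "CKSAAP", "CTRIAD", "CTDC", "CTDT", "CTDD", "QSORDER")


@dataclass(frozen=True)
class DescriptorVector:
    parent_id: str
    descriptor_id: str
    values: np.ndarray
    params: dict | None = None

    @property
    def dim(self) -> int:
        return self.values.size


def _clean(sequence: str, descriptor: str) -> str:
    """Uppercase, map nonstandard letters to X, drop X from counted positions."""
    seq = sequence.upper()
    seq = "".join("X" if a not in _AA_INDEX else a for a in seq)
    cleaned = seq.replace("X", "")
    if not cleaned:
        raise ValueError(f"{descriptor}: no standard residues in sequence")
    return cleaned


def aac(sequence: str, parent_id: str = "") -> DescriptorVector:
    """Amino-acid composition: 20 residue frequencies summing to 1."""
    seq = _clean(sequence, "AAC")
    counts = np.zeros(20)
    for a in seq:
        counts[_AA_INDEX[a]] += 1
    return DescriptorVector(parent_id, "AAC", counts / len(seq))


def dde(sequence: str, parent_id: str = "") -> DescriptorVector:
    """Dipeptide deviation from expected mean.

    For each of the 400 dipeptides: DDE = (Dc - Tm) / sqrt(Tv), with the
    observed dipeptide frequency Dc over the N-1 adjacent pairs, the
    codon-based theoretical mean Tm = (C_i/61)(C_j/61), and variance
    Tv = Tm (1 - Tm) / (N - 1).
    """
    seq = _clean(sequence, "DDE")
    n_pairs = len(seq) - 1
    if n_pairs < 1:
        raise ValueError("DDE requires at least 2 standard residues")
    dc = np.zeros(400)
    for i in range(n_pairs):
        dc[_AA_INDEX[seq[i]] * 20 + _AA_INDEX[seq[i + 1]]] += 1
    dc /= n_pairs
    tm = np.array(
        [
            (_CODON_COUNTS[a] / 61.0) * (_CODON_COUNTS[b] / 61.0)
            for a in AMINO_ACIDS
            for b in AMINO_ACIDS
        ]
    )
    tv = tm * (1.0 - tm) / n_pairs
    return DescriptorVector(parent_id, "DDE", (dc - tm) / np.sqrt(tv))


def cksaap(sequence: str, kmax: int = 3, parent_id: str = "") -> DescriptorVector:
    """Composition of k-spaced amino-acid pairs for k = 0..kmax.

    One 400-entry block per gap k, each normalized by its valid pair
    count so every block sums to 1.
    """
    seq = _clean(sequence, "CKSAAP")
    if len(seq) < kmax + 2:
        raise ValueError(f"CKSAAP with kmax={kmax} requires length >= {kmax + 2}")
    blocks = []
    for k in range(kmax + 1):
        counts = np.zeros(400)
        n_pairs = len(seq) - k - 1
        for i in range(n_pairs):
            counts[_AA_INDEX[seq[i]] * 20 + _AA_INDEX[seq[i + k + 1]]] += 1
        blocks.append(counts / n_pairs)
    return DescriptorVector(parent_id, "CKSAAP", np.concatenate(blocks),
                            {"kmax": kmax})


def ctriad(sequence: str, parent_id: str = "") -> DescriptorVector:
    """Conjoint triad: frequencies of class triples over the 7 residue classes."""
    seq = _clean(sequence, "CTRIAD")
    if len(seq) < 3:
        raise ValueError("CTriad requires at least 3 standard residues")
    cls = {a: c for c, group in enumerate(_TRIAD_CLASSES) for a in group}
    counts = np.zeros(343)
    for i in range(len(seq) - 2):
        counts[cls[seq[i]] * 49 + cls[seq[i + 1]] * 7 + cls[seq[i + 2]]] += 1
    return DescriptorVector(parent_id, "CTRIAD", counts / (len(seq) - 2))


def _ctd_classes(seq: str, prop: str) -> np.ndarray:
    groups = _CTD_GROUPS[prop]
    cls = {a: c for c, group in enumerate(groups) for a in group}
    return np.array([cls[a] for a in seq], dtype=int)


def ctd(sequence: str, parent_id: str = "") -> tuple[
    DescriptorVector, DescriptorVector, DescriptorVector
]:
    """Composition (21), transition (21) and distribution (105) descriptors.

    For each of 7 physicochemical properties the sequence is mapped to
    three classes; CTDC gives per-class fractions (each property triplet
    sums to 1), CTDT the fraction of adjacent positions that switch
    between each unordered class pair, CTDD the relative positions (%)
    of the first, 25%, 50%, 75% and last occurrence of each class.
    """
    seq = _clean(sequence, "CTD")
    L = len(seq)
    comp, trans, dist = [], [], []
    for prop in _CTD_PROPERTIES:
        classes = _ctd_classes(seq, prop)
        for c in range(3):
            comp.append(float(np.mean(classes == c)))
        if L < 2:
            trans.extend([0.0, 0.0, 0.0])
        else:
            pairs = np.stack([classes[:-1], classes[1:]])
            lo, hi = pairs.min(0), pairs.max(0)
            for a, b in ((0, 1), (0, 2), (1, 2)):
                trans.append(float(np.mean((lo == a) & (hi == b))))
        for c in range(3):
            pos = np.flatnonzero(classes == c) + 1  # 1-based
            if pos.size == 0:
                dist.extend([0.0] * 5)
            else:
                for frac in (0.0, 0.25, 0.50, 0.75, 1.0):
                    rank = max(1, int(np.ceil(frac * pos.size)))
                    dist.append(100.0 * pos[rank - 1] / L)
    return (
        DescriptorVector(parent_id, "CTDC", np.array(comp)),
        DescriptorVector(parent_id, "CTDT", np.array(trans)),
        DescriptorVector(parent_id, "CTDD", np.array(dist)),
    )


def qsorder(
    sequence: str, nlag: int = 30, w: float = 0.1, parent_id: str = ""
) -> DescriptorVector:
    """Quasi-sequence-order descriptor, dimension 2*(20 + nlag).

    For each of the two physicochemical distance matrices: the
    sequence-order coupling numbers tau_d = sum_i dist(r_i, r_{i+d})^2
    for d = 1..nlag, then 20 weighted composition terms
    f_a / (sum f + w sum tau) followed by nlag order terms
    w tau_d / (sum f + w sum tau).
    """
    seq = _clean(sequence, "QSOrder")
    L = len(seq)
    if L <= nlag:
        raise ValueError(f"QSOrder with nlag={nlag} requires length > {nlag}")
    codes = np.array([_AA_INDEX[a] for a in seq])
    counts = np.bincount(codes, minlength=20).astype(float)
    parts = []
    for dm in _DISTANCE_MATRICES:
        tau = np.array(
            [np.sum(dm[codes[:-d], codes[d:]] ** 2) for d in range(1, nlag + 1)]
        )
        denom = counts.sum() + w * tau.sum()
        parts.append(counts / denom)
        parts.append(w * tau / denom)
    return DescriptorVector(parent_id, "QSORDER", np.concatenate(parts),
                            {"nlag": nlag, "w": w})


_SINGLE = {
    "AAC": aac,
    "DDE": dde,
    "CKSAAP": cksaap,
    "CTRIAD": ctriad,
    "QSORDER": qsorder,
}


def compute_descriptor(sequence: str, descriptor_id: str,
                       parent_id: str = "", **params) -> DescriptorVector:
    """Dispatch a single descriptor by id (CTDC/CTDT/CTDD select one of the CTD trio)."""
    descriptor_id = descriptor_id.upper()
    if descriptor_id in ("CTDC", "CTDT", "CTDD"):
        trio = ctd(sequence, parent_id)
        return trio[("CTDC", "CTDT", "CTDD").index(descriptor_id)]
    if descriptor_id not in _SINGLE:
        raise ValueError(f"unknown descriptor {descriptor_id!r}")
    allowed = {"CKSAAP": ("kmax",), "QSORDER": ("nlag", "w")}.get(descriptor_id, ())
    kwargs = {k: v for k, v in params.items() if k in allowed}
    return _SINGLE[descriptor_id](sequence, parent_id=parent_id, **kwargs)


def compose_descriptors(sequence: str, descriptor_ids: list[str],
                        parent_id: str = "", **params) -> DescriptorVector:
    """Concatenate descriptors in the given order (e.g. AAC + CKSAAP)."""
    if not descriptor_ids:
        raise ValueError("at least one descriptor id required")
    parts = [compute_descriptor(sequence, d, parent_id, **params) for d in descriptor_ids]
    return DescriptorVector(
        parent_id,
        "+".join(d.upper() for d in descriptor_ids),
        np.concatenate([p.values for p in parts]),
    )
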