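"""Cross-sequence, cross-model multi-view featurization.

A protein sequence is windowed into terminal views — the first and last
1,022 residues (plus an optional central window) — and each view is
embedded by one or more backends into a fixed-length vector by mean
pooling over residue positions.  The per-(backend, view) vectors are
concatenated in a fixed layout into the fused feature: with two
1,280-dim backends and the dual (N, C) scheme the fused space is
5,120-dimensional.

Sequences at or below the window length yield identical N- and C-views
(the block is duplicated rather than padded), which keeps the fused
width constant across a dataset of mixed lengths.

Backends: ``esm1b`` and ``esm2`` are adapters over external pretrained
checkpoints and require ``torch`` + ``fair-esm``; the ``mock`` backend
is a deterministic, sequence-sensitive stand-in (k-mer counts through a
seeded random projection) that needs no download and keeps synthetic
class motifs linearly detectable downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import AMINO_ACIDS, ProteinRecord

MAX_VIEW_LEN = 1022
ESM_DIM = 1280


class ViewTag(str, Enum):
    N_TERM = "N_TERM"
    C_TERM = "C_TERM"
    CENTER = "CENTER"


class BackendUnavailableError(RuntimeError):
    """A pretrained-checkpoint backend cannot run in this installation."""


@dataclass(frozen=True)
class SequenceView:
    """A windowed segment of a parent sequence (1-based inclusive coords)."""

    parent_id: str
    tag: ViewTag
    residues: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if len(self.residues) != self.end - self.start + 1:
            raise ValueError("residues length inconsistent with coordinates")


@dataclass(frozen=True)
class EmbedderSpec:
    backend_id: str  # esm1b | esm2 | mock (mock ids may carry a suffix: mock2, ...)
    output_dim: int
    seed: int = 0  # used by the mock backend only
    pooling: str = "MEAN_RESIDUE"

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        if self.backend_id not in ("esm1b", "esm2") and not self.backend_id.startswith("mock"):
            raise ValueError(f"unknown backend {self.backend_id!r}")
        if self.backend_id in ("esm1b", "esm2") and self.output_dim != ESM_DIM:
            raise ValueError(
                f"{self.backend_id} emits {ESM_DIM}-dim pooled vectors; "
                f"got output_dim={self.output_dim}"
            )


@dataclass(frozen=True)
class EmbeddingVector:
    parent_id: str
    view_tag: ViewTag
    backend_id: str
    values: np.ndarray


@dataclass(frozen=True)
class FusedFeature:
    parent_id: str
    values: np.ndarray
    layout: tuple[tuple[str, ViewTag], ...]  # ordered (backend_id, view_tag) blocks


def extract_views(
    record: ProteinRecord, scheme: str = "dual", max_len: int = MAX_VIEW_LEN
) -> list[SequenceView]:
    """Window a record into terminal (and optionally central) views.

    ``single`` → [N]; ``dual`` → [N, C]; ``tri`` → [N, C, CENTER].
    Every view has length ``min(L, max_len)``.  The central window is
    centred on the sequence midpoint and clipped to the sequence.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    L = len(record)
    w = min(L, max_len)
    seq = record.sequence
    n_view = SequenceView(record.id, ViewTag.N_TERM, seq[:w], 1, w)
    if scheme == "single":
        return [n_view]
    c_view = SequenceView(record.id, ViewTag.C_TERM, seq[L - w:], L - w + 1, L)
    if scheme == "dual":
        return [n_view, c_view]
    if scheme == "tri":
        start0 = min(max(0, L // 2 - w // 2), L - w)  # 0-based, clipped
        center = SequenceView(
            record.id, ViewTag.CENTER, seq[start0:start0 + w], start0 + 1, start0 + w
        )
        return [n_view, c_view, center]
    raise ValueError(f"unknown view scheme {scheme!r} (expected single/dual/tri)")


# ---------------------------------------------------------------------------
# mock backend

_KMAX = 3
_ALPHABET = AMINO_ACIDS + "X"
_INDEX = {a: i for i, a in enumerate(_ALPHABET)}
_A = len(_ALPHABET)
#: count bins: 1-, 2- and 3-mers over the 21-letter alphabet
_N_BINS = _A + _A**2 + _A**3
_projection_cache: dict[tuple[int, int], np.ndarray] = {}


def _kmer_counts(residues: str) -> np.ndarray:
    """Concatenated 1/2/3-mer count vector (nonstandard letters → X)."""
    codes = np.array(
        [_INDEX.get(a, _INDEX["X"]) for a in residues], dtype=np.int64
    )
    counts = np.zeros(_N_BINS)
    offset = 0
    idx = np.zeros(0, dtype=np.int64)
    for k in range(1, _KMAX + 1):
        if len(codes) >= k:
            if k == 1:
                idx = codes.copy()
            else:
                idx = idx[:-1] * _A + codes[k - 1:]
            np.add.at(counts, offset + idx, 1.0)
        offset += _A**k
    return counts


def _projection(output_dim: int, seed: int) -> np.ndarray:
    key = (output_dim, seed)
    if key not in _projection_cache:
        rng = np.random.default_rng(np.random.SeedSequence([seed, output_dim, 0x6D6F636B]))
        _projection_cache[key] = rng.standard_normal((_N_BINS, output_dim)) / np.sqrt(_N_BINS)
    return _projection_cache[key]


def mock_embed(residues: str, output_dim: int, seed: int = 0) -> np.ndarray:
    """Deterministic sequence-sensitive embedding: k-mer counts through a
    fixed seed-derived Gaussian projection, length-normalized to unit norm."""
    if not residues:
        raise ValueError("cannot embed an empty sequence")
    if output_dim < 1:
        raise ValueError("output_dim must be >= 1")
    v = _kmer_counts(residues) @ _projection(output_dim, seed)
    norm = np.linalg.norm(v)
    if norm == 0.0:  # unreachable for nonempty input, kept as a guard
        raise ValueError("degenerate zero embedding")
    return v / norm


# ---------------------------------------------------------------------------
# pretrained-checkpoint adapters

def _esm_embed(residues: str, backend_id: str) -> np.ndarray:  # pragma: no cover
    """Mean-pooled final-layer representation from a pretrained ESM model.

    Requires ``torch`` and ``fair-esm`` with a locally available
    checkpoint; pooling averages residue positions, excluding the
    begin/end special tokens.
    """
    try:
        import esm  # type: ignore
        import torch  # type: ignore
    except ImportError as exc:
        raise BackendUnavailableError(
            f"backend {backend_id!r} needs the 'torch' and 'fair-esm' packages "
            "with a pretrained checkpoint; install them or use backend 'mock'"
        ) from exc
    loader = {
        "esm1b": esm.pretrained.esm1b_t33_650M_UR50S,
        "esm2": esm.pretrained.esm2_t33_650M_UR50D,
    }[backend_id]
    try:
        model, alphabet = loader()
    except Exception as exc:
        raise BackendUnavailableError(
            f"could not load the {backend_id} checkpoint ({exc}); "
            "use backend 'mock' for a download-free run"
        ) from exc
    model.eval()
    batch_converter = alphabet.get_batch_converter()
    _, _, tokens = batch_converter([("seq", residues)])
    with torch.no_grad():
        reps = model(tokens, repr_layers=[33])["representations"][33]
    return reps[0, 1:len(residues) + 1].mean(0).numpy()


def embed_view(view: SequenceView, spec: EmbedderSpec) -> EmbeddingVector:
    """Embed one view into a fixed-length pooled vector."""
    if not view.residues:
        raise ValueError("empty view")
    if len(view.residues) > MAX_VIEW_LEN:
        raise ValueError(f"view longer than {MAX_VIEW_LEN} residues")
    if spec.backend_id.startswith("mock"):
        values = mock_embed(view.residues, spec.output_dim, spec.seed)
    else:
        values = _esm_embed(view.residues, spec.backend_id)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite embedding for {view.parent_id}/{view.tag}")
    return EmbeddingVector(view.parent_id, view.tag, spec.backend_id, values)


def fuse_views(
    embeddings: Sequence[EmbeddingVector],
    layout: Sequence[tuple[str, ViewTag]],
) -> FusedFeature:
    """Concatenate per-(backend, view) embeddings in fixed layout order.

    The input list order is irrelevant; ``layout`` dictates block order.
    """
    parents = {e.parent_id for e in embeddings}
    if len(parents) != 1:
        raise ValueError(f"embeddings from multiple parents: {sorted(parents)}")
    table = {(e.backend_id, e.view_tag): e for e in embeddings}
    if len(table) != len(embeddings):
        dupes = [k for k in table if sum(
            1 for e in embeddings if (e.backend_id, e.view_tag) == k) > 1]
        raise ValueError(f"duplicated embedding block(s): {dupes}")
    blocks = []
    for key in layout:
        key = (key[0], ViewTag(key[1]))
        if key not in table:
            raise ValueError(f"missing embedding block {key}")
        blocks.append(table[key].values)
    extra = set(table) - {(b, ViewTag(v)) for b, v in layout}
    if extra:
        raise ValueError(f"embedding block(s) not in layout: {sorted(extra)}")
    return FusedFeature(
        parent_id=next(iter(parents)),
        values=np.concatenate(blocks),
        layout=tuple((b, ViewTag(v)) for b, v in layout),
    )


_SCHEME_TAGS = {
    "single": (ViewTag.N_TERM,),
    "dual": (ViewTag.N_TERM, ViewTag.C_TERM),
    "tri": (ViewTag.N_TERM, ViewTag.C_TERM, ViewTag.CENTER),
}


def default_layout(
    scheme: str, specs: Sequence[EmbedderSpec]
) -> tuple[tuple[str, ViewTag], ...]:
    """Backend-major block order: all views of backend 1, then backend 2, ...

    For the dual scheme with (esm1b, esm2) this is
    (esm1b, N), (esm1b, C), (esm2, N), (esm2, C).
    """
    if scheme not in _SCHEME_TAGS:
        raise ValueError(f"unknown view scheme {scheme!r}")
    return tuple(
        (spec.backend_id, tag) for spec in specs for tag in _SCHEME_TAGS[scheme]
    )


def _cache_key(record: ProteinRecord, view: SequenceView, spec: EmbedderSpec) -> str:
    payload = "|".join(
        [
            hashlib.sha256(view.residues.encode()).hexdigest(),
            spec.backend_id,
            str(spec.output_dim),
            str(spec.seed),
            view.tag.value,
            f"{view.start}-{view.end}",
            spec.pooling,
        ]
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def embed_dataset(
    records: Sequence[ProteinRecord],
    scheme: str = "dual",
    specs: Sequence[EmbedderSpec] = (),
    cache_dir: str | Path | None = None,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Fused feature table: one row per record, columns ``f0000..``.

    With a ``cache_dir``, per-view embeddings are cached on disk keyed by
    (sequence hash, backend, view coordinates, pooling); reruns reuse
    cached vectors and log ``cached`` instead of recomputing.
    """
    if not records:
        raise ValueError("no records to embed")
    if not specs:
        raise ValueError("at least one EmbedderSpec required")
    layout = default_layout(scheme, specs)
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    for record in records:
        try:
            views = {v.tag: v for v in extract_views(record, scheme)}
            embeddings = []
            for spec in specs:
                for tag in _SCHEME_TAGS[scheme]:
                    view = views[tag]
                    vec = None
                    key_path = None
                    if cache is not None:
                        key_path = cache / f"{_cache_key(record, view, spec)}.npy"
                        if key_path.exists():
                            vec = np.load(key_path)
                            if log is not None:
                                log.append(f"cached {record.id} {spec.backend_id} {tag.value}")
                    if vec is None:
                        vec = embed_view(view, spec).values
                        if key_path is not None:
                            np.save(key_path, vec)
                        if log is not None:
                            log.append(f"computed {record.id} {spec.backend_id} {tag.value}")
                    embeddings.append(
                        EmbeddingVector(record.id, tag, spec.backend_id, vec)
                    )
            rows.append(fuse_views(embeddings, layout).values)
        except Exception as exc:
            raise type(exc)(f"record {record.id!r}: {exc}") from exc
    matrix = np.vstack(rows)
    return pd.DataFrame(
        matrix,
        index=[r.id for r in records],
        columns=[f"f{i:04d}" for i in range(matrix.shape[1])],
    )


def write_feature_table(table: pd.DataFrame, path: str | Path,
                        metadata: dict | None = None) -> None:
    """TSV feature table (id + numeric columns) with a JSON metadata sidecar."""
    path = Path(path)
    table.to_csv(path, sep="\t", index_label="id")
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(metadata, indent=1))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
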