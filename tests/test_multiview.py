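"""Terminal-window views, mock embeddings and feature fusion."""

import numpy as np
import pytest

from mhcview.data_io import ProteinRecord
from mhcview.multiview import (
    BackendUnavailableError,
    EmbedderSpec,
    SequenceView,
    ViewTag,
    embed_dataset,
    embed_view,
    extract_views,
    fuse_views,
    mock_embed,
)

from conftest import random_sequence


def _record(rng, length, ident="x", label=1):
    return ProteinRecord(ident, random_sequence(rng, length), label)


class TestExtractViews:
    def test_long_sequence_dual_windows(self, rng):
        record = _record(rng, 2000)
        n, c = extract_views(record, "dual")
        assert (n.start, n.end) == (1, 1022)
        assert (c.start, c.end) == (979, 2000)
        assert len(n.residues) == len(c.residues) == 1022
        assert n.residues == record.sequence[:1022]
        assert c.residues == record.sequence[-1022:]

    def test_boundary_length_views_coincide(self, rng):
        record = _record(rng, 1022)
        n, c = extract_views(record, "dual")
        assert n.residues == c.residues == record.sequence

    def test_short_sequence_duplicated(self, rng):
        record = _record(rng, 500)
        n, c = extract_views(record, "dual")
        assert n.residues == c.residues == record.sequence
        assert (n.start, n.end) == (c.start, c.end) == (1, 500)

    def test_schemes(self, rng):
        record = _record(rng, 3000)
        assert [v.tag for v in extract_views(record, "single")] == [ViewTag.N_TERM]
        assert [v.tag for v in extract_views(record, "dual")] == [
            ViewTag.N_TERM, ViewTag.C_TERM]
        tri = extract_views(record, "tri")
        assert [v.tag for v in tri] == [ViewTag.N_TERM, ViewTag.C_TERM, ViewTag.CENTER]
        center = tri[2]
        assert len(center.residues) == 1022
        assert center.start == 3000 // 2 - 511 + 1

    def test_view_length_law(self, rng):
        for L in (1, 10, 1021, 1022, 1023, 5000):
            record = _record(rng, L)
            for view in extract_views(record, "tri"):
                assert len(view.residues) == min(L, 1022)

    def test_unknown_scheme_rejected(self, rng):
        with pytest.raises(ValueError, match="scheme"):
            extract_views(_record(rng, 10), "quad")


class TestMockEmbed:
    def test_deterministic(self):
        a = mock_embed("AAAA", 16, seed=7)
        b = mock_embed("AAAA", 16, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_unit_norm(self, rng):
        for _ in range(10):
            seq = random_sequence(rng, int(rng.integers(1, 300)))
            v = mock_embed(seq, 32, seed=0)
            assert v.shape == (32,)
            assert np.isclose(np.linalg.norm(v), 1.0)

    def test_no_collisions_across_random_sequences(self, rng):
        seqs = {random_sequence(rng, 50) for _ in range(220)}
        seqs = list(seqs)[:200]
        vecs = np.stack([mock_embed(s, 48, seed=1) for s in seqs])
        dists = np.linalg.norm(vecs[:, None] - vecs[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        assert dists.min() > 1e-8

    def test_single_residue_sensitivity(self, rng):
        base = random_sequence(rng, 80)
        spec = EmbedderSpec("mock", 64, seed=0)
        view = SequenceView("p", ViewTag.N_TERM, base, 1, 80)
        ref = embed_view(view, spec).values
        for _ in range(100):
            pos = int(rng.integers(0, 80))
            new = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(0, 20))]
            if new == base[pos]:
                continue
            mutated = base[:pos] + new + base[pos + 1:]
            mview = SequenceView("p", ViewTag.N_TERM, mutated, 1, 80)
            assert not np.array_equal(embed_view(mview, spec).values, ref)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mock_embed("", 8, seed=0)


class TestEmbedView:
    def test_dimension_and_determinism(self, rng):
        view = SequenceView("p", ViewTag.N_TERM, random_sequence(rng, 40), 1, 40)
        spec = EmbedderSpec("mock", 64, seed=3)
        a = embed_view(view, spec)
        b = embed_view(view, spec)
        assert a.values.shape == (64,)
        assert np.all(np.isfinite(a.values))
        np.testing.assert_array_equal(a.values, b.values)

    def test_esm_backend_unavailable_mentions_mock(self, rng):
        view = SequenceView("p", ViewTag.N_TERM, random_sequence(rng, 10), 1, 10)
        with pytest.raises(BackendUnavailableError, match="mock"):
            embed_view(view, EmbedderSpec("esm1b", 1280))

    def test_esm_spec_rejects_wrong_dim(self):
        with pytest.raises(ValueError, match="1280"):
            EmbedderSpec("esm2", 512)


class TestFuseViews:
    def _embeddings(self, rng, dims=(64, 64, 64, 64)):
        layout = [("esm1b", ViewTag.N_TERM), ("esm1b", ViewTag.C_TERM),
                  ("esm2", ViewTag.N_TERM), ("esm2", ViewTag.C_TERM)]
        from mhcview.multiview import EmbeddingVector
        embs = [
            EmbeddingVector("p", tag, backend, rng.standard_normal(d))
            for (backend, tag), d in zip(layout, dims)
        ]
        return embs, layout

    def test_paper_configuration_width(self, rng):
        embs, layout = self._embeddings(rng, dims=(1280,) * 4)
        fused = fuse_views(embs, layout)
        assert fused.values.shape == (5120,)

    def test_mock_width(self, rng):
        embs, layout = self._embeddings(rng)
        assert fuse_views(embs, layout).values.shape == (256,)

    def test_input_order_irrelevant(self, rng):
        embs, layout = self._embeddings(rng)
        a = fuse_views(embs, layout)
        b = fuse_views(embs[::-1], layout)
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_block_named(self, rng):
        embs, layout = self._embeddings(rng)
        with pytest.raises(ValueError, match="missing"):
            fuse_views(embs[:3], layout)

    def test_parent_mismatch_rejected(self, rng):
        from mhcview.multiview import EmbeddingVector
        embs, layout = self._embeddings(rng)
        embs[0] = EmbeddingVector("other", embs[0].view_tag, embs[0].backend_id,
                                  embs[0].values)
        with pytest.raises(ValueError, match="parents"):
            fuse_views(embs, layout)


class TestEmbedDataset:
    def test_shape_contract(self, rng):
        records = [_record(rng, 100, f"r{i}") for i in range(10)]
        specs = [EmbedderSpec("mock", 64, seed=0), EmbedderSpec("mock2", 64, seed=1)]
        table = embed_dataset(records, "dual", specs)
        assert table.shape == (10, 256)
        assert list(table.index) == [r.id for r in records]

    def test_single_scheme_width(self, rng):
        records = [_record(rng, 100, f"r{i}") for i in range(3)]
        table = embed_dataset(records, "single", [EmbedderSpec("mock", 32)])
        assert table.shape == (3, 32)

    def test_warm_cache_identical_and_logged(self, rng, tmp_path):
        records = [_record(rng, 60, f"r{i}") for i in range(4)]
        specs = [EmbedderSpec("mock", 16, seed=0)]
        log1, log2 = [], []
        a = embed_dataset(records, "dual", specs, cache_dir=tmp_path, log=log1)
        b = embed_dataset(records, "dual", specs, cache_dir=tmp_path, log=log2)
        assert (a.values == b.values).all()
        assert all(e.startswith("computed") for e in log1)
        assert all(e.startswith("cached") for e in log2)

    def test_end_to_end_determinism(self, rng):
        records = [_record(rng, 1500, f"r{i}") for i in range(5)]
        specs = [EmbedderSpec("mock", 32, seed=4)]
        a = embed_dataset(records, "dual", specs)
        b = embed_dataset(records, "dual", specs)
        assert (a.values == b.values).all()
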