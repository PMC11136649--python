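import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panelmix import (
    FingerprintMismatchError,
    FixtureSpec,
    PanelError,
    PermutationState,
    SamplerParams,
    TransformMetadata,
    apply_event,
    forward_transform,
    initial_shuffle,
    make_toy_map,
    reverse_transform,
    simulate_mosaic_panel,
    validate_panel,
)
from panelmix.breakpoints import BreakpointSet
from panelmix.transform import _apply_to_rows, replay_events

from conftest import make_panel


class TestPermutationState:
    def test_non_bijection_rejected(self):
        with pytest.raises(ValueError):
            PermutationState(order=np.array([0, 0, 2]))

    def test_apply_event_swaps(self):
        state = PermutationState(order=np.array([0, 1, 2]))
        apply_event(state, 0, 2)
        np.testing.assert_array_equal(state.order, [2, 1, 0])

    def test_self_swap_is_noop(self):
        state = PermutationState(order=np.array([2, 0, 1]))
        apply_event(state, 1, 1)
        np.testing.assert_array_equal(state.order, [2, 0, 1])

    def test_double_swap_is_involution(self):
        state = PermutationState(order=np.array([3, 1, 0, 2]))
        apply_event(apply_event(state, 0, 3), 0, 3)
        np.testing.assert_array_equal(state.order, [3, 1, 0, 2])

    def test_out_of_range_rejected(self):
        state = PermutationState(order=np.array([0, 1]))
        with pytest.raises(IndexError):
            apply_event(state, 0, 2)


class TestInitialShuffle:
    def test_deterministic(self):
        a = initial_shuffle(20, np.random.default_rng(5)).order
        b = initial_shuffle(20, np.random.default_rng(5)).order
        np.testing.assert_array_equal(a, b)

    def test_uniform_for_n2(self):
        """Identity and swap each appear ~50% over many seeds (Fisher-Yates)."""
        n_id = sum(
            initial_shuffle(2, np.random.default_rng(s)).order[0] == 0
            for s in range(10_000)
        )
        se = np.sqrt(0.25 / 10_000)
        assert n_id / 10_000 == pytest.approx(0.5, abs=3 * se)

    @settings(derandomize=True, max_examples=25)
    @given(n=st.integers(2, 300), seed=st.integers(0, 2**31 - 1))
    def test_always_a_bijection(self, n, seed):
        state = initial_shuffle(n, np.random.default_rng(seed))
        assert np.array_equal(np.sort(state.order), np.arange(n))


class TestForwardTransform:
    def test_hand_traced_single_breakpoint(self):
        """Two haplotypes, one swap at bp 250: alleles exchange from site 3 on."""
        panel = make_panel(
            np.array([[0, 1], [0, 1], [0, 1], [0, 1]]),
            positions=[100, 200, 300, 400],
        )
        state = PermutationState(order=np.array([0, 1]))  # identity shuffle
        bset = BreakpointSet(
            positions_bp=np.array([250.0]), positions_cM=np.array([0.5]),
            params=SamplerParams(K=1, N=2, seed=0), lam=1.0,
        )
        pairs = np.array([[0, 1]])
        rows = zip(panel.variants.itertuples(index=False), panel.matrix)
        out = np.array([r for _, r in _apply_to_rows(rows, state, bset, pairs, False)])
        np.testing.assert_array_equal(out[:, 0], [0, 0, 1, 1])
        np.testing.assert_array_equal(out[:, 1], [1, 1, 0, 0])

    def test_event_at_variant_position_applies_after(self):
        """Boundary rule: an event exactly at a variant's bp acts after it."""
        panel = make_panel(np.array([[0, 1], [0, 1]]), positions=[100, 200])
        state = PermutationState(order=np.array([0, 1]))
        bset = BreakpointSet(
            positions_bp=np.array([100.0]), positions_cM=np.array([0.0]),
            params=SamplerParams(K=1, N=2, seed=0), lam=1.0,
        )
        rows = zip(panel.variants.itertuples(index=False), panel.matrix)
        out = np.array([
            r for _, r in _apply_to_rows(rows, state, bset, np.array([[0, 1]]), False)
        ])
        np.testing.assert_array_equal(out, [[0, 1], [1, 0]])

    def test_k0_is_global_relabeling(self, small_panel, megabase_map):
        params = SamplerParams(K=0, N=small_panel.n_haplotypes, seed=9)
        syn, meta = forward_transform(small_panel, megabase_map, params)
        assert meta.chromosomes[0].n_breakpoints == 0
        # one column permutation applied at every site
        order, _, _ = replay_events(megabase_map, params, "1")
        np.testing.assert_array_equal(syn.matrix, small_panel.matrix[:, order.order])

    @pytest.mark.parametrize("k", [0, 1, 8, 128])
    def test_allele_counts_invariant(self, small_panel, megabase_map, k):
        params = SamplerParams(K=k, N=small_panel.n_haplotypes, seed=k + 1)
        syn, _ = forward_transform(small_panel, megabase_map, params)
        np.testing.assert_array_equal(
            (syn.matrix > 0).sum(axis=1), (small_panel.matrix > 0).sum(axis=1)
        )
        assert syn.n_sites == small_panel.n_sites
        assert syn.n_haplotypes == small_panel.n_haplotypes

    def test_synthetic_sample_ids_replace_originals(self, small_panel, megabase_map):
        params = SamplerParams(K=1, N=small_panel.n_haplotypes, seed=0)
        syn, _ = forward_transform(small_panel, megabase_map, params)
        assert all(s.startswith("SYN") for s in syn.sample_ids)
        assert not set(syn.sample_ids) & set(small_panel.sample_ids)

    def test_determinism(self, small_panel, megabase_map):
        params = SamplerParams(K=8, N=small_panel.n_haplotypes, seed=77)
        a, _ = forward_transform(small_panel, megabase_map, params)
        b, _ = forward_transform(small_panel, megabase_map, params)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_n_mismatch_rejected(self, small_panel, megabase_map):
        with pytest.raises(PanelError):
            forward_transform(small_panel, megabase_map, SamplerParams(K=1, N=10, seed=0))

    def test_unsorted_positions_rejected(self, megabase_map):
        panel = make_panel(np.zeros((2, 4)), positions=[100, 200])
        panel.variants.loc[0, "pos"] = 500  # corrupt after construction
        with pytest.raises(PanelError):
            forward_transform(
                panel, megabase_map, SamplerParams(K=1, N=4, seed=0)
            )

    def test_streaming_rows_processed_lazily(self, megabase_map):
        """The row pipeline pulls one site at a time (O(N) resident state)."""
        from collections import namedtuple

        Var = namedtuple("Var", ["chrom", "pos", "ref", "alt"])
        params = SamplerParams(K=8, N=4, seed=0)
        state, bset, pairs = replay_events(megabase_map, params, "1")
        pulled = []

        def rows():
            for s in range(5000):
                pulled.append(s)
                yield Var("1", s * 100 + 1, "A", "C"), np.zeros(4, dtype=np.int8)

        stream = _apply_to_rows(rows(), state, bset, pairs, False)
        for emitted, _ in enumerate(stream):
            assert len(pulled) == emitted + 1  # never more than one row ahead
            if emitted >= 200:
                break


class TestReverseTransform:
    @pytest.mark.parametrize("k", [0, 1, 8, 128])
    def test_round_trip_identity(self, megabase_map, k):
        panel = simulate_mosaic_panel(
            FixtureSpec(n_haplotypes=40, n_sites=120, seed=k + 10)
        )
        params = SamplerParams(K=k, N=40, seed=k + 99)
        syn, meta = forward_transform(panel, megabase_map, params)
        back = reverse_transform(syn, megabase_map, meta)
        np.testing.assert_array_equal(back.matrix, panel.matrix)

    def test_wrong_seed_does_not_restore(self, megabase_map):
        panel = simulate_mosaic_panel(FixtureSpec(n_haplotypes=50, n_sites=200, seed=1))
        params = SamplerParams(K=8, N=50, seed=123)
        syn, meta = forward_transform(panel, megabase_map, params)
        bad = TransformMetadata(seed=124, K=8, N=50, chromosomes=meta.chromosomes)
        back = reverse_transform(syn, megabase_map, bad)
        assert not np.array_equal(back.matrix, panel.matrix)

    def test_fingerprint_mismatch_refused(self, megabase_map, hotspot_map):
        panel = simulate_mosaic_panel(FixtureSpec(n_haplotypes=20, n_sites=50, seed=2))
        params = SamplerParams(K=8, N=20, seed=5)
        syn, meta = forward_transform(panel, megabase_map, params)
        with pytest.raises(FingerprintMismatchError):
            reverse_transform(syn, hotspot_map, meta)

    def test_n_mismatch_refused(self, megabase_map):
        panel = simulate_mosaic_panel(FixtureSpec(n_haplotypes=20, n_sites=50, seed=2))
        meta = TransformMetadata(seed=0, K=1, N=99)
        with pytest.raises(PanelError):
            reverse_transform(panel, megabase_map, meta)


class TestMultiChromosome:
    def _two_chrom_panel(self):
        rng = np.random.default_rng(0)
        mat = (rng.random((60, 20)) < 0.4).astype(np.int8)
        variants = pd.DataFrame(
            {
                "chrom": ["1"] * 30 + ["2"] * 30,
                "pos": np.concatenate([np.arange(30), np.arange(30)]) * 10_000 + 1,
                "ref": "A",
                "alt": "C",
            }
        )
        from panelmix import HaplotypePanel
        return HaplotypePanel(
            variants=variants, matrix=mat, sample_ids=[f"S{i}" for i in range(10)]
        )

    def test_per_chromosome_round_trip(self):
        panel = self._two_chrom_panel()
        maps = {
            "1": make_toy_map((1, 300_000), 0.5, "constant", chromosome="1"),
            "2": make_toy_map((1, 300_000), 0.5, "hotspot", chromosome="2"),
        }
        params = SamplerParams(K=32, N=20, seed=4)
        syn, meta = forward_transform(panel, maps, params)
        assert {r.chromosome for r in meta.chromosomes} == {"1", "2"}
        back = reverse_transform(syn, maps, meta)
        np.testing.assert_array_equal(back.matrix, panel.matrix)

    def test_substreams_differ_across_chromosomes(self):
        panel = self._two_chrom_panel()
        gmap1 = make_toy_map((1, 300_000), 0.5, "constant", chromosome="1")
        gmap2 = make_toy_map((1, 300_000), 0.5, "constant", chromosome="2")
        params = SamplerParams(K=0, N=20, seed=4)
        order1, _, _ = replay_events(gmap1, params, "1")
        order2, _, _ = replay_events(gmap2, params, "2")
        assert not np.array_equal(order1.order, order2.order)

    def test_missing_map_for_chromosome(self):
        panel = self._two_chrom_panel()
        maps = {"1": make_toy_map((1, 300_000), 0.5, "constant", chromosome="1")}
        with pytest.raises(PanelError):
            forward_transform(panel, maps, SamplerParams(K=1, N=20, seed=0))


class TestMetadata:
    def test_json_round_trip(self, tmp_path, small_panel, megabase_map):
        params = SamplerParams(K=8, N=50, seed=13)
        _, meta = forward_transform(small_panel, megabase_map, params)
        path = tmp_path / "meta.json"
        meta.to_json(path)
        assert TransformMetadata.from_json(path) == meta

    def test_header_line_round_trip(self, small_panel, megabase_map):
        params = SamplerParams(K=8, N=50, seed=13)
        _, meta = forward_transform(small_panel, megabase_map, params)
        assert TransformMetadata.from_header_lines(meta.header_lines()) == meta

    def test_header_without_metadata_raises(self):
        with pytest.raises(PanelError):
            TransformMetadata.from_header_lines(["##fileformat=VCFv4.2"])


class TestValidation:
    def test_clean_fixture_reports_zero_problems(self, small_panel):
        report = validate_panel(small_panel, strict=True)
        assert report.n_missing_sites == 0
        assert report.n_unphased_sites == 0

    def test_missing_genotype_fatal_in_strict(self):
        panel = make_panel(np.array([[0, 1, -1, 0]]))
        with pytest.raises(PanelError):
            validate_panel(panel, strict=True)
        report = validate_panel(panel, strict=False)
        assert report.n_missing_sites == 1

    def test_monomorphic_counted_not_fatal(self):
        panel = make_panel(np.array([[0, 0, 0, 0], [0, 1, 0, 1]]))
        report = validate_panel(panel, strict=True)
        assert report.n_monomorphic == 1
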