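import math

import numpy as np
import pytest

from confens import (
    ConformerEnsemble,
    TorsionEnsembleSpec,
    aggregate_by_bins,
    evaluate_ensemble,
    filter_energy_window,
    generate_torsion_ensemble,
    make_reference,
    truncate_ensemble,
)
from confens.ensemble import EvaluationResult


@pytest.fixture
def pentane_ensemble():
    return generate_torsion_ensemble(
        TorsionEnsembleSpec(template="alkane_chain(5)", states_per_rotor=3, seed=1)
    )


def with_energies(e, energies):
    confs = [
        type(c)(coords=c.coords, energy=float(E), name=c.name)
        for c, E in zip(e.conformers, energies)
    ]
    return ConformerEnsemble(molecule=e.molecule, conformers=confs)


class TestEnergyWindow:
    def test_zero_window_keeps_only_global_minimum_ties(self, pentane_ensemble):
        e = with_energies(pentane_ensemble, [0.0, 0.0, 1.0, 2.0, 3.0, 1.5, 0.5, 2.5, 4.0])
        kept = filter_energy_window(e, 0.0)
        assert [c.energy for c in kept.conformers] == [0.0, 0.0]

    def test_inclusive_boundary(self, pentane_ensemble):
        e = with_energies(
            pentane_ensemble, [0.0, 4.9, 5.0, 5.1, 9.0, 9.1, 9.2, 9.3, 9.4]
        )
        kept = filter_energy_window(e, 5.0)
        assert [c.energy for c in kept.conformers] == [0.0, 4.9, 5.0]

    def test_infinite_window_is_identity(self, pentane_ensemble):
        kept = filter_energy_window(pentane_ensemble, math.inf)
        assert kept.conformers == pentane_ensemble.conformers

    def test_missing_energy_names_conformer(self, pentane_ensemble):
        e = pentane_ensemble
        e.conformers[3].energy = None
        with pytest.raises(ValueError, match="conformer 3"):
            filter_energy_window(e, 5.0)

    def test_keep_sets_are_nested_in_window(self, pentane_ensemble):
        previous = set()
        for w in [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 25, 30]:
            kept = {c.name for c in filter_energy_window(pentane_ensemble, w).conformers}
            assert previous <= kept
            previous = kept


class TestTruncation:
    def test_below_cap_unchanged(self, pentane_ensemble):
        out = truncate_ensemble(pentane_ensemble, max_confs=100_000)
        assert len(out) == len(pentane_ensemble)
        assert not out.truncated_100k

    def test_forced_truncation_keeps_prefix_and_flags(self, pentane_ensemble):
        out = truncate_ensemble(pentane_ensemble, max_confs=4)
        assert len(out) == 4
        assert out.conformers == pentane_ensemble.conformers[:4]
        assert out.truncated_100k

    def test_flag_propagates_into_evaluation(self, pentane_ensemble):
        out = truncate_ensemble(pentane_ensemble, max_confs=4)
        ref = make_reference(out, pick=0).conformer
        res = evaluate_ensemble(out, ref, compute_st=False)
        assert res.truncated_100k

    def test_pipeline_order_truncate_then_window(self, pentane_ensemble):
        # truncation keeps the generation-order prefix; the window then acts
        # on the surviving energies. The reverse order can keep different
        # conformers: pin the documented composition.
        e = with_energies(pentane_ensemble, [5.0, 0.0, 1.0, 6.0, 0.2, 9.0, 0.1, 7.0, 0.3])
        a = filter_energy_window(truncate_ensemble(e, max_confs=4), 1.0)
        b = truncate_ensemble(filter_energy_window(e, 1.0), max_confs=4)
        assert [c.energy for c in a.conformers] == [0.0, 1.0]
        assert [c.energy for c in b.conformers] == [0.0, 1.0, 0.2, 0.1]


class TestEvaluate:
    def test_self_containment_gives_zero_rmsd_and_unit_st(self, pentane_ensemble):
        ref = make_reference(pentane_ensemble, pick=2).conformer
        res = evaluate_ensemble(pentane_ensemble, ref)
        assert res.min_rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.max_st == pytest.approx(1.0, abs=1e-3)
        assert res.argmin_rmsd == 2

    def test_argmin_matches_exhaustive_oracle(self, pentane_ensemble):
        from confens.superpose import min_rmsd

        ref = make_reference(pentane_ensemble, pick=5, perturb_sd=0.05, seed=9).conformer
        res = evaluate_ensemble(pentane_ensemble, ref, compute_st=False)
        oracle = [
            min_rmsd(c, ref, pentane_ensemble.molecule).rmsd
            for c in pentane_ensemble.conformers
        ]
        assert res.argmin_rmsd == int(np.argmin(oracle))
        assert res.min_rmsd == pytest.approx(min(oracle), abs=1e-12)

    def test_singleton_ensemble(self, pentane_ensemble):
        single = ConformerEnsemble(
            molecule=pentane_ensemble.molecule,
            conformers=[pentane_ensemble.conformers[0]],
        )
        ref = make_reference(pentane_ensemble, pick=3).conformer
        res = evaluate_ensemble(single, ref, compute_st=False)
        assert res.n_conformers == 1

    def test_empty_ensemble_is_an_error(self, pentane_ensemble):
        empty = ConformerEnsemble(molecule=pentane_ensemble.molecule, conformers=[])
        with pytest.raises(ValueError, match="empty"):
            evaluate_ensemble(empty, pentane_ensemble.conformers[0])

    def test_min_rmsd_monotone_as_conformers_added(self, pentane_ensemble):
        ref = make_reference(pentane_ensemble, pick=7, perturb_sd=0.2, seed=3).conformer
        prev = np.inf
        for k in range(1, len(pentane_ensemble) + 1):
            sub = ConformerEnsemble(
                molecule=pentane_ensemble.molecule,
                conformers=pentane_ensemble.conformers[:k],
            )
            res = evaluate_ensemble(sub, ref, compute_st=False)
            assert res.min_rmsd <= prev + 1e-12
            prev = res.min_rmsd


def make_result(name, rmsd, st, nha, er, truncated=False):
    return EvaluationResult(
        name=name, min_rmsd=rmsd, max_st=st, argmin_rmsd=0, argmax_st=0,
        n_conformers=1, truncated_100k=truncated, n_nha=nha, n_er=er,
    )


class TestAggregation:
    def test_identical_results_give_that_value_in_every_bin(self):
        results = [make_result(f"m{k}", 0.5, 0.9, 10, 2.0) for k in range(4)]
        table = aggregate_by_bins(results, by="nha")
        assert len(table) == 1
        assert table["mean_min_rmsd"].iloc[0] == pytest.approx(0.5)
        assert table["count"].iloc[0] == 4

    def test_half_up_binning_of_effective_rotors(self):
        results = [make_result("a", 0.4, 0.9, 10, 2.4), make_result("b", 0.6, 0.8, 10, 2.6)]
        table = aggregate_by_bins(results, by="er")
        assert table["bin"].tolist() == [2, 3]

    def test_exclusion_flag_removes_exactly_truncated(self):
        results = [
            make_result("a", 0.4, 0.9, 10, 2.0, truncated=False),
            make_result("b", 1.4, 0.5, 10, 2.0, truncated=True),
        ]
        full = aggregate_by_bins(results, by="nha")
        trimmed = aggregate_by_bins(results, by="nha", exclude_truncated=True)
        assert full["count"].iloc[0] == 2
        assert trimmed["count"].iloc[0] == 1
        assert trimmed["mean_min_rmsd"].iloc[0] == pytest.approx(0.4)

    def test_empty_bins_are_omitted(self):
        results = [make_result("a", 0.4, 0.9, 5, 1.0), make_result("b", 0.8, 0.7, 30, 9.0)]
        table = aggregate_by_bins(results, by="nha")
        assert table["bin"].tolist() == [5, 30]
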