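"""Data splitting, member subsampling, and training contracts.

The heavier checks (checkpoint integrity, learning a clean phantom task)
run a small real training job on noiseless high-contrast phantoms; the
split/subsample logic is exercised with lightweight dummy cases.
"""

import numpy as np
import pytest

from pkdseg.imaging_io import Case
from pkdseg.grids import VoxelGrid3D, BinaryMask3D
from pkdseg.network import NetworkSpec
from pkdseg.phantoms import PhantomSpec
from pkdseg.experiments import make_cases
from pkdseg.trainer import (
    TrainConfig, TrainedMember, revalidate_member, split_cases,
    subsample_for_member, train_ensemble, train_member,
)


def dummy_cases(n):
    vals = np.zeros((4, 4, 2), dtype=np.float32)
    mask = np.zeros((4, 4, 2), dtype=np.uint8)
    return [
        Case(f"c{i}", VoxelGrid3D(vals, (1.5, 1.5, 3.0)),
             BinaryMask3D(mask, (1.5, 1.5, 3.0)))
        for i in range(n)
    ]


class TestSplitCases:
    def test_80_20_split_of_ten(self):
        tr, va = split_cases(dummy_cases(10), 0.8, seed=1)
        assert len(tr) == 8 and len(va) == 2
        ids = {c.case_id for c in tr} | {c.case_id for c in va}
        assert len(ids) == 10  # disjoint and exhaustive

    def test_deterministic_for_seed(self):
        cases = dummy_cases(10)
        a = split_cases(cases, 0.8, seed=3)
        b = split_cases(cases, 0.8, seed=3)
        assert [c.case_id for c in a[0]] == [c.case_id for c in b[0]]
        c = split_cases(cases, 0.8, seed=4)
        assert [x.case_id for x in a[0]] != [x.case_id for x in c[0]]

    def test_degenerate_two_cases(self):
        tr, va = split_cases(dummy_cases(2), 0.99, seed=0)
        assert len(tr) == 1 and len(va) == 1

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            split_cases(dummy_cases(1), 0.8, seed=0)


class TestSubsampleForMember:
    def test_cardinality_and_uniqueness(self):
        sub = subsample_for_member(dummy_cases(100), 0, seed=1, subset_fraction=0.8)
        assert len(sub) == 80
        assert len({c.case_id for c in sub}) == 80

    def test_members_draw_different_subsets(self):
        cases = dummy_cases(100)
        s0 = {c.case_id for c in subsample_for_member(cases, 0, seed=1)}
        s1 = {c.case_id for c in subsample_for_member(cases, 1, seed=1)}
        assert s0 != s1

    def test_full_fraction_returns_everything_in_order(self):
        cases = dummy_cases(10)
        sub = subsample_for_member(cases, 3, seed=1, subset_fraction=1.0)
        assert [c.case_id for c in sub] == [c.case_id for c in cases]


@pytest.fixture(scope="module")
def clean_training_run(noiseless_phantom_spec_module):
    """One pinned small training job on noiseless phantoms, reused below."""
    cases = make_cases(7, noiseless_phantom_spec_module, seed=123)
    tr, va = cases[:5], cases[5:]
    member = train_member(
        NetworkSpec(depth=2, base_filters=8), tr, va,
        TrainConfig(epochs=20, seed=11),
    )
    return member, tr, va


@pytest.fixture(scope="module")
def noiseless_phantom_spec_module():
    return PhantomSpec(noise_sd=0.0, bias_field_amplitude=0.0,
                       border_contrast_jitter=0.0, liver_confounder_prob=0.0)


class TestTrainMember:
    def test_history_length_and_best_epoch_argmax(self, clean_training_run):
        member, _, _ = clean_training_run
        assert len(member.history) == 20
        val = [v for _, v in member.history]
        assert member.best_epoch == int(np.argmax(val))

    def test_checkpoint_reproduces_best_val_dice(self, clean_training_run):
        member, _, va = clean_training_run
        again = revalidate_member(member, va)
        assert again == pytest.approx(member.best_val_dice, abs=1e-5)

    def test_best_so_far_val_dice_nondecreasing(self, clean_training_run):
        member, _, _ = clean_training_run
        val = [v for _, v in member.history]
        running = np.maximum.accumulate(val)
        assert np.all(np.diff(running) >= 0)

    def test_learns_clean_task_to_high_dice(self, clean_training_run):
        member, _, _ = clean_training_run
        assert member.best_val_dice >= 0.95

    def test_beats_all_zero_prediction(self, clean_training_run):
        # all-zero prediction scores ~0 soft-Dice on nonempty targets
        member, _, _ = clean_training_run
        assert member.best_val_dice > 0.5

    def test_best_epoch_argmax_contract_on_synthetic_history(self):
        member = TrainedMember(
            net_spec=NetworkSpec(depth=1, base_filters=1),
            weights=[], history=[(0.2, 0.3), (0.5, 0.7), (0.6, 0.6)],
            best_epoch=1, member_seed=0,
        )
        assert member.best_val_dice == 0.7

    def test_overlapping_split_rejected(self, noiseless_phantom_spec_module):
        cases = make_cases(3, noiseless_phantom_spec_module, seed=5)
        with pytest.raises(ValueError):
            train_member(NetworkSpec(depth=1, base_filters=2),
                         cases[:2], cases[1:], TrainConfig(epochs=1, seed=0))

    def test_save_load_roundtrip(self, clean_training_run, tmp_path):
        member, _, va = clean_training_run
        member.save(tmp_path / "member_00")
        loaded = TrainedMember.load(tmp_path / "member_00")
        assert loaded.best_epoch == member.best_epoch
        assert loaded.history == pytest.approx(member.history)
        assert revalidate_member(loaded, va) == pytest.approx(
            member.best_val_dice, abs=1e-5
        )


class TestTrainEnsemble:
    def test_even_k_rejected(self, noiseless_phantom_spec_module):
        cases = make_cases(4, noiseless_phantom_spec_module, seed=5)
        with pytest.raises(ValueError):
            train_ensemble(cases, 2, NetworkSpec(depth=1, base_filters=2),
                           TrainConfig(epochs=1, seed=0))

    def test_members_have_distinct_seeds_and_finite_dice(
        self, noiseless_phantom_spec_module
    ):
        cases = make_cases(6, noiseless_phantom_spec_module, seed=8)
        ens = train_ensemble(
            cases, 3, NetworkSpec(depth=1, base_filters=2),
            TrainConfig(epochs=2, seed=4, batch_size=16),
        )
        seeds = [m.member_seed for m in ens.members]
        assert len(set(seeds)) == 3
        for m in ens.members:
            assert np.isfinite(m.best_val_dice)
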