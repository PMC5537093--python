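"""Training orchestration: splits, per-member training with
best-validation-Dice checkpointing, and the K-member ensemble loop.

Each ensemble member sees its own random subset of the cases and its own
80/20 train/validation split, mimicking a panel of human observers who each
learned from different examples.  Weights are checkpointed at the epoch
with the best validation soft-Dice (earliest epoch on ties) — the returned
member carries those weights, not the final-epoch ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging_io import Case
from .network import NetworkSpec, UNet2D, build_network, normalize_volume
from .nn_core import Adam

__all__ = [
    "TrainConfig", "TrainedMember", "TrainingDivergedError",
    "split_cases", "subsample_for_member", "train_member", "train_ensemble",
    "cases_to_slices",
]


class TrainingDivergedError(RuntimeError):
    """Non-finite loss encountered; message carries the epoch index."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    The checkpoint metric is the validation soft-Dice, maximized.
    """

    epochs: int = 100
    split_fraction: float = 0.8
    batch_size: int = 4
    learning_rate: float = 2e-3
    subset_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.subset_fraction <= 1):
            raise ValueError("subset_fraction must lie in (0, 1]")


@dataclass
class TrainedMember:
    """One trained observer: checkpointed weights plus training history."""

    net_spec: NetworkSpec
    weights: list
    history: list = field(default_factory=list)  # [(train_dice, val_dice), ...]
    best_epoch: int = 0
    member_seed: int = 0
    val_case_ids: list = field(default_factory=list)
    _model: UNet2D | None = field(default=None, repr=False, compare=False)

    @property
    def best_val_dice(self) -> float:
        return self.history[self.best_epoch][1]

    def model(self) -> UNet2D:
        """Model carrying the checkpointed weights (built lazily, cached)."""
        if self._model is None:
            self._model = build_network(self.net_spec, seed=self.member_seed)
            self._model.set_weights(self.weights)
        return self._model

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history, columns=["train_dice", "val_dice"]).rename_axis("epoch")

    # -- persistence: .npz weights + JSON sidecar ---------------------------
    def save(self, path_prefix) -> tuple[Path, Path]:
        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        npz_path = prefix.with_suffix(".npz")
        json_path = prefix.with_suffix(".json")
        np.savez(npz_path, **{f"w{i}": w for i, w in enumerate(self.weights)})
        sidecar = dict(
            net_spec=self.net_spec.to_dict(),
            member_seed=self.member_seed,
            best_epoch=self.best_epoch,
            history=[[float(a), float(b)] for a, b in self.history],
            val_case_ids=list(self.val_case_ids),
        )
        json_path.write_text(json.dumps(sidecar, indent=1))
        return npz_path, json_path

    @classmethod
    def load(cls, path_prefix) -> "TrainedMember":
        prefix = Path(path_prefix)
        npz_path = prefix.with_suffix(".npz")
        json_path = prefix.with_suffix(".json")
        for p in (npz_path, json_path):
            if not p.exists():
                raise FileNotFoundError(f"missing checkpoint file: {p}")
        sidecar = json.loads(json_path.read_text())
        with np.load(npz_path) as data:
            weights = [data[f"w{i}"] for i in range(len(data.files))]
        return cls(
            net_spec=NetworkSpec.from_dict(sidecar["net_spec"]),
            weights=weights,
            history=[tuple(h) for h in sidecar["history"]],
            best_epoch=int(sidecar["best_epoch"]),
            member_seed=int(sidecar["member_seed"]),
            val_case_ids=list(sidecar.get("val_case_ids", [])),
        )


def _derive_member_seed(seed: int, member_index: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(member_index)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def split_cases(cases: list, fraction: float, seed: int):
    """Deterministic disjoint/exhaustive split; >= 1 case on each side."""
    n = len(cases)
    if n < 2:
        raise ValueError("need at least 2 cases to split")
    n_train = int(np.clip(round(fraction * n), 1, n - 1))
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = sorted(perm[:n_train])
    val_idx = sorted(perm[n_train:])
    return [cases[i] for i in train_idx], [cases[i] for i in val_idx]


def subsample_for_member(cases: list, member_index: int, seed: int,
                         subset_fraction: float = 0.8) -> list:
    """Member-specific random subset, drawn without replacement.

    The draw is seeded by (seed, member_index), so different members see
    different subsets while the whole procedure stays reproducible.  Case
    order is preserved.
    """
    if member_index < 0:
        raise ValueError("member_index must be >= 0")
    n = len(cases)
    size = int(np.clip(round(subset_fraction * n), 1, n))
    if size == 0 or n == 0:
        raise ValueError("subsample would be empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(member_index)]))
    idx = sorted(rng.choice(n, size=size, replace=False))
    return [cases[i] for i in idx]


def cases_to_slices(cases: list) -> tuple[np.ndarray, np.ndarray]:
    """Stack all axial slices of all cases into (N, 1, X, Y) arrays.

    Images are z-score normalized per volume before slicing.
    """
    xs, ts = [], []
    for case in cases:
        vol = normalize_volume(case.image.values)
        msk = case.reference_mask.values
        for z in range(vol.shape[2]):
            xs.append(vol[:, :, z])
            ts.append(msk[:, :, z])
    x = np.stack(xs)[:, None].astype(np.float32)
    t = np.stack(ts)[:, None].astype(np.float32)
    return x, t


def _eval_global_dice(model: UNet2D, x: np.ndarray, t: np.ndarray,
                      batch_size: int = 16) -> float:
    """Validation soft-Dice aggregated over all voxels of all slices."""
    inter = 0.0
    denom = 0.0
    for i in range(0, len(x), batch_size):
        p = model.predict_proba(x[i : i + batch_size])
        tb = t[i : i + batch_size]
        inter += float((p * tb).sum())
        denom += float(p.sum() + tb.sum())
    smooth = 1e-6
    return (2.0 * inter + smooth) / (denom + smooth)


def train_member(net_spec: NetworkSpec, train_cases: list, val_cases: list,
                 config: TrainConfig) -> TrainedMember:
    """Train one network, checkpointing the best validation soft-Dice epoch."""
    if not train_cases or not val_cases:
        raise ValueError("train and validation sets must be nonempty")
    train_ids = {c.case_id for c in train_cases}
    if train_ids & {c.case_id for c in val_cases}:
        raise ValueError("train and validation sets overlap")

    x_tr, t_tr = cases_to_slices(train_cases)
    x_va, t_va = cases_to_slices(val_cases)

    model = build_network(net_spec, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xD1CE]))

    history: list[tuple[float, float]] = []
    best_val = -np.inf
    best_epoch = 0
    best_weights = model.get_weights()

    n = len(x_tr)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        dice_sum, weight_sum = 0.0, 0
        for i in range(0, n, config.batch_size):
            batch = order[i : i + config.batch_size]
            try:
                d = model.dice_loss_backward(x_tr[batch], t_tr[batch])
            except FloatingPointError as exc:
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}"
                ) from exc
            opt.step(model.gradients())
            dice_sum += d * len(batch)
            weight_sum += len(batch)
        train_dice = dice_sum / weight_sum
        val_dice = _eval_global_dice(model, x_va, t_va)
        if not np.isfinite(val_dice):
            raise TrainingDivergedError(f"non-finite validation Dice at epoch {epoch}")
        history.append((float(train_dice), float(val_dice)))
        if val_dice > best_val:  # strict: earliest epoch wins ties
            best_val = val_dice
            best_epoch = epoch
            best_weights = model.get_weights()

    return TrainedMember(
        net_spec=net_spec,
        weights=best_weights,
        history=history,
        best_epoch=best_epoch,
        member_seed=int(config.seed),
        val_case_ids=[c.case_id for c in val_cases],
    )


def revalidate_member(member: TrainedMember, val_cases: list) -> float:
    """Re-evaluate the checkpointed weights on a validation set.

    Used to confirm checkpoint integrity: on the original validation cases
    this reproduces ``member.best_val_dice`` up to float accumulation.
    """
    x_va, t_va = cases_to_slices(val_cases)
    return _eval_global_dice(member.model(), x_va, t_va)


def train_ensemble(cases: list, k: int, net_spec: NetworkSpec, config: TrainConfig,
                   progress: bool = False):
    """Train K members on distinct case subsets; returns an EnsembleModel.

    K must be odd so majority voting has no ties.
    """
    from .ensemble import EnsembleModel

    if k < 1 or k % 2 == 0:
        raise ValueError(f"ensemble size must be odd and >= 1, got {k}")
    members = []
    for i in range(k):
        member_seed = _derive_member_seed(config.seed, i)
        subset = subsample_for_member(cases, i, config.seed, config.subset_fraction)
        tr, va = split_cases(subset, config.split_fraction, member_seed)
        member_cfg = replace(config, seed=member_seed)
        member = train_member(net_spec, tr, va, member_cfg)
        members.append(member)
        if progress:
            print(f"member {i}: best val Dice {member.best_val_dice:.4f} "
                  f"at epoch {member.best_epoch}")
    return EnsembleModel(members=members)
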