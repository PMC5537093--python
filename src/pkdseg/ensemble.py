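"""The artificial multi-observer: member inference and majority voting.

Each trained network acts as an independent observer; its probability map
is binarized at 0.5 and the K binary opinions are fused per voxel by
strict majority (>= floor(K/2)+1 of K votes, K odd).  Averaging member
probabilities before thresholding is available as an alternative fusion
rule but is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import VoxelGrid3D, BinaryMask3D, GeometryError
from .network import normalize_volume
from .trainer import TrainedMember

__all__ = ["EnsembleModel", "predict_member", "binarize", "majority_vote", "segment"]


def predict_member(member: TrainedMember, image: VoxelGrid3D,
                   batch_size: int = 16) -> np.ndarray:
    """Per-voxel kidney probabilities for a volume, slice by slice.

    The volume is z-score normalized, each axial slice is pushed through
    the network in inference mode (dropout off), and the slice maps are
    restacked into a 3-D probability array shaped like the input.
    """
    vol = normalize_volume(image.values)
    X, Y, Z = vol.shape
    slices = vol.transpose(2, 0, 1)[:, None]  # (Z, 1, X, Y)
    model = member.model()
    probs = np.empty((Z, X, Y), dtype=np.float32)
    for i in range(0, Z, batch_size):
        probs[i : i + batch_size] = model.predict_proba(slices[i : i + batch_size])[:, 0]
    return probs.transpose(1, 2, 0)


def binarize(prob: np.ndarray, threshold: float = 0.5,
             spacing_mm=(1.5, 1.5, 3.0)) -> BinaryMask3D:
    """Threshold a probability map; a voxel is kidney iff p > threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    return BinaryMask3D((np.asarray(prob) > threshold).astype(np.uint8), spacing_mm)


def majority_vote(masks: list[BinaryMask3D]) -> BinaryMask3D:
    """Per-voxel strict-majority fusion of K binary masks, K odd."""
    k = len(masks)
    if k < 1 or k % 2 == 0:
        raise ValueError(f"majority voting needs an odd number of masks, got {k}")
    first = masks[0]
    for m in masks[1:]:
        if m.shape != first.shape or m.spacing_mm != first.spacing_mm:
            raise GeometryError("all masks must share shape and spacing")
    votes = np.zeros(first.shape, dtype=np.int32)
    for m in masks:
        votes += m.values
    need = k // 2 + 1
    return BinaryMask3D((votes >= need).astype(np.uint8), first.spacing_mm)


@dataclass
class EnsembleModel:
    """K trained members plus the voting rule."""

    members: list
    binarize_threshold: float = 0.5
    vote_on_probabilities: bool = False

    def __post_init__(self):
        k = len(self.members)
        if k < 1 or k % 2 == 0:
            raise ValueError(f"ensemble size must be odd and >= 1, got {k}")

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def vote_threshold(self) -> int:
        return self.k // 2 + 1

    def member_probabilities(self, image: VoxelGrid3D) -> list[np.ndarray]:
        return [predict_member(m, image) for m in self.members]

    def vote(self, prob_maps: list[np.ndarray], spacing_mm) -> BinaryMask3D:
        if self.vote_on_probabilities:
            mean = np.mean(np.stack(prob_maps), axis=0)
            return binarize(mean, self.binarize_threshold, spacing_mm)
        member_masks = [
            binarize(p, self.binarize_threshold, spacing_mm) for p in prob_maps
        ]
        return majority_vote(member_masks)

    # -- persistence --------------------------------------------------------
    def save(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, member in enumerate(self.members):
            member.save(out_dir / f"member_{i:02d}")
        meta = dict(
            k=self.k,
            binarize_threshold=self.binarize_threshold,
            vote_on_probabilities=self.vote_on_probabilities,
        )
        (out_dir / "ensemble.json").write_text(json.dumps(meta, indent=1))
        return out_dir

    @classmethod
    def load(cls, in_dir) -> "EnsembleModel":
        in_dir = Path(in_dir)
        meta_path = in_dir / "ensemble.json"
        if not meta_path.exists():
            raise FileNotFoundError(f"missing ensemble metadata: {meta_path}")
        meta = json.loads(meta_path.read_text())
        members = [
            TrainedMember.load(in_dir / f"member_{i:02d}") for i in range(meta["k"])
        ]
        return cls(
            members=members,
            binarize_threshold=meta["binarize_threshold"],
            vote_on_probabilities=meta["vote_on_probabilities"],
        )


def segment(ensemble: EnsembleModel, image: VoxelGrid3D, postprocess: bool = True,
            postprocess_options: dict | None = None) -> BinaryMask3D:
    """Full automated segmentation: member inference, voting, cleanup.

    With ``postprocess`` the voted mask is reduced to its two largest
    connected components and the borders are refined by the edge-based
    active contour (applied once, to the voted mask).
    """
    prob_maps = ensemble.member_probabilities(image)
    voted = ensemble.vote(prob_maps, image.spacing_mm)
    if postprocess:
        from .postprocess import postprocess_mask

        voted = postprocess_mask(voted, image, **(postprocess_options or {}))
    return voted
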