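"""Multi-rater label fusion and ROI grouping utilities.

Consensus labeling fuses specimen-level subregion segmentations by
voxelwise plurality voting, optionally regularized by a Potts-model Markov
random field prior optimized with iterated conditional modes (ICM) from the
majority-vote initialization. ROI groupings define the analysis subregions:
the 14 combined MTL subregions (entorhinal, BA35 and BA36 subdivisions and
the pre/parasubiculum merged) or the entorhinal subfields, where the
olfactory (Eo) and rostral (ER) subfields are reported but excluded from
quantitative summaries because their anterior extent falls outside the
atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set

import numpy as np

from .atlas import ERC_SUBFIELD_CODES, LABEL_TABLE

__all__ = [
    "RoiGrouping",
    "consensus_labels",
    "analysis_roi_set",
    "pairing_rule",
    "COMBINED_14",
]

_NAME_TO_CODE = {v: k for k, v in LABEL_TABLE.items()}

# The 14 combined analysis subregions
COMBINED_14 = (
    "S",
    "PrS-PaS",
    "SRLM",
    "PP",
    "CA1",
    "CA2",
    "CA3",
    "DG",
    "ERC",
    "BA35",
    "BA36",
    "TE",
    "TF",
    "TH",
)


@dataclass(frozen=True)
class RoiGrouping:
    """An analysis ROI: a named set of subregion label codes.

    ``excluded_codes`` are reported alongside the ROI but never enter
    summary statistics.
    """

    name: str
    member_codes: frozenset = field(default_factory=frozenset)
    excluded_codes: frozenset = field(default_factory=frozenset)


def analysis_roi_set(mode: str) -> List[RoiGrouping]:
    """Return the ROI groupings for a given analysis mode.

    ``combined_14``: the 14 combined MTL subregions, with the eight
    entorhinal subfields merged into a single ERC ROI. ``erc_subfields``:
    the six analyzed entorhinal subfields (EMI, EI, ELr, ELc, EC, ECL),
    with Eo and ER marked excluded.
    """
    if mode == "combined_14":
        out = []
        for name in COMBINED_14:
            if name == "ERC":
                codes = frozenset(ERC_SUBFIELD_CODES)
            else:
                codes = frozenset({_NAME_TO_CODE[name]})
            out.append(RoiGrouping(name=name, member_codes=codes))
        return out
    if mode == "erc_subfields":
        excluded = frozenset({_NAME_TO_CODE["Eo"], _NAME_TO_CODE["ER"]})
        out = []
        for name in ("EMI", "EI", "ELr", "ELc", "EC", "ECL"):
            out.append(
                RoiGrouping(
                    name=name,
                    member_codes=frozenset({_NAME_TO_CODE[name]}),
                    excluded_codes=excluded,
                )
            )
        return out
    raise ValueError(f"unknown ROI mode: {mode!r}")


def pairing_rule(roi: str) -> str:
    """Burden-source ROI for a thickness ROI.

    The SRLM and perforant pathway contain no neurons and accumulate no
    tangles; their thickness is paired with the burden of the neighboring
    CA1 and the structurally connected ERC respectively. Every other ROI
    pairs with itself.
    """
    known = set(COMBINED_14) | {"EMI", "EI", "ELr", "ELc", "EC", "ECL"}
    if roi not in known:
        raise ValueError(f"unknown analysis ROI: {roi!r}")
    if roi == "SRLM":
        return "CA1"
    if roi == "PP":
        return "ERC"
    return roi


def _majority_vote(counts: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Plurality label per voxel; ties break toward the smallest code.

    ``counts`` has shape (n_codes, *grid); codes are sorted ascending, so
    argmax's first-hit tie-breaking realizes the smallest-code rule.
    """
    return codes[np.argmax(counts, axis=0)]


def consensus_labels(
    votes: Sequence[np.ndarray],
    mrf_beta: float = 0.1,
    max_iter: int = 10,
) -> np.ndarray:
    """Fuse rater label volumes into a consensus labeling.

    With ``mrf_beta = 0`` the output is the exact voxelwise plurality label
    (ties toward the smallest code). With ``mrf_beta > 0`` the labeling
    maximizes the vote-count log-likelihood plus a 6-neighborhood Potts
    smoothness term, beta per agreeing neighbor on the log-count scale,
    via ICM initialized at the majority vote; iteration stops at
    convergence or ``max_iter`` sweeps.
    """
    if len(votes) == 0:
        raise ValueError("empty vote list")
    if mrf_beta < 0:
        raise ValueError("mrf_beta must be >= 0")
    shape = votes[0].shape
    for v in votes:
        if v.shape != shape:
            raise ValueError("all vote volumes must share the template grid")
    stack = np.stack([np.asarray(v) for v in votes], axis=0)
    codes = np.unique(stack)
    counts = np.stack([(stack == c).sum(axis=0) for c in codes], axis=0)
    labeling = _majority_vote(counts, codes)
    if mrf_beta == 0:
        return labeling

    # log-likelihood of each candidate label per voxel; a small pseudo-count
    # keeps zero-vote labels finitely penalized
    n = stack.shape[0]
    alpha = 0.01
    loglik = np.log((counts + alpha) / (n + alpha * len(codes)))

    code_index = {int(c): k for k, c in enumerate(codes)}
    for _ in range(max_iter):
        changed = 0
        # count agreeing 6-neighbors for every candidate label
        agree = np.zeros_like(loglik, dtype=float)
        for k, c in enumerate(codes):
            is_c = labeling == c
            acc = np.zeros(shape, dtype=float)
            for axis in range(3):
                for shift in (-1, 1):
                    rolled = np.roll(is_c, shift, axis=axis).astype(float)
                    sl = [slice(None)] * 3
                    sl[axis] = 0 if shift == 1 else -1
                    rolled[tuple(sl)] = 0.0
                    acc += rolled
            agree[k] = acc
        score = loglik + mrf_beta * agree
        new_labeling = codes[np.argmax(score, axis=0)]
        changed = int((new_labeling != labeling).sum())
        labeling = new_labeling
        if changed == 0:
            break
    return labeling
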