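"""From model weights to per-bond scores and heat-map colors.

A bond's raw score is the sum of the weights of every feature occurrence
whose bond set contains the bond (attachment-point bonds included). Scores
are normalized to [0,1] either against the whole training set (full_set) or
against the molecule itself (single_molecule), then mapped onto a
red -> orange -> green gradient built from two linear sub-gradients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chem_io import Molecule
from .fingerprint import ProvenancedFingerprint
from .model import LinearModel

logger = logging.getLogger(__name__)

MODES = ("full_set", "single_molecule")


class ColoringError(Exception):
    pass


class NormalizationError(ColoringError):
    pass


class GradientRangeError(ColoringError):
    pass


@dataclass
class BondScoreMap:
    """Raw additive bond scores for one molecule (default 0 for bonds no
    feature covers)."""

    molecule: Molecule
    scores: dict[int, float]
    size_normalized: bool = False

    def values(self) -> list[float]:
        return [self.scores[b] for b in sorted(self.scores)]


@dataclass(frozen=True)
class NormalizationContext:
    mode: str
    s_min: float
    s_max: float

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise NormalizationError(f"unknown mode {self.mode!r}")
        if self.s_min > self.s_max:
            raise NormalizationError("s_min must be <= s_max")


@dataclass(frozen=True)
class Gradient:
    """Three-anchor gradient; channels are integers in 0..255."""

    negative_color: tuple[int, int, int] = (255, 0, 0)
    mid_color: tuple[int, int, int] = (255, 165, 0)
    positive_color: tuple[int, int, int] = (0, 200, 0)

    def __post_init__(self) -> None:
        for color in (self.negative_color, self.mid_color, self.positive_color):
            if any(not (0 <= c <= 255) for c in color):
                raise ValueError(f"RGB channels out of range: {color}")


DEFAULT_GRADIENT = Gradient()


@dataclass(frozen=True)
class BondColor:
    raw: float
    nu: float
    rgb: tuple[int, int, int]

    @property
    def hex(self) -> str:
        r, g, b = self.rgb
        return f"#{r:02x}{g:02x}{b:02x}"


@dataclass
class BondColoring:
    molecule: Molecule
    entries: dict[int, BondColor] = field(default_factory=dict)

    def nu_of(self, bond_index: int) -> float:
        return self.entries[bond_index].nu

    def to_rows(self) -> list[dict]:
        rows = []
        for b in sorted(self.entries):
            e = self.entries[b]
            rows.append(
                {
                    "molecule": self.molecule.name,
                    "bond_index": b,
                    "raw_score": e.raw,
                    "normalized_score": e.nu,
                    "color": e.hex,
                }
            )
        return rows


def bond_scores(
    model: LinearModel,
    fp: ProvenancedFingerprint,
    size_normalize: bool = False,
) -> BondScoreMap:
    """Additive per-bond score from all feature occurrences covering a bond.

    With ``size_normalize`` each occurrence contributes w/|B(f)| per bond,
    spreading a feature's weight equally over its bonds; default is off.
    Contributions are summed with ``math.fsum`` so the result is independent
    of accumulation order.
    """
    model.check_config(fp)
    contributions: dict[int, list[float]] = {
        b.index: [] for b in fp.molecule.bonds
    }
    for fid in fp.present_features:
        w = model.weights.get(fid, 0.0)
        for occ in fp.provenance[fid]:
            if size_normalize:
                if not occ.member_bonds:
                    continue
                share = w / len(occ.member_bonds)
            else:
                share = w
            for b in occ.member_bonds:
                contributions[b].append(share)
    scores = {b: math.fsum(parts) for b, parts in contributions.items()}
    return BondScoreMap(molecule=fp.molecule, scores=scores, size_normalized=size_normalize)


def atom_scores(model: LinearModel, fp: ProvenancedFingerprint) -> dict[int, float]:
    """Analogous additive score per atom (not used by the default renderer)."""
    model.check_config(fp)
    contributions: dict[int, list[float]] = {a: [] for a in range(fp.molecule.n_atoms)}
    for fid in fp.present_features:
        w = model.weights.get(fid, 0.0)
        for occ in fp.provenance[fid]:
            for a in occ.member_atoms:
                contributions[a].append(w)
    return {a: math.fsum(parts) for a, parts in contributions.items()}


def normalization_context(
    mode: str, scoremaps: Sequence[BondScoreMap]
) -> NormalizationContext:
    """Build the (s_min, s_max) scaling context.

    full_set pools scores over every supplied map (training set plus
    compounds of interest); single_molecule requires exactly one map.
    """
    if mode not in MODES:
        raise NormalizationError(f"unknown mode {mode!r}")
    if not scoremaps:
        raise NormalizationError("no score maps supplied")
    if mode == "single_molecule" and len(scoremaps) != 1:
        raise NormalizationError(
            "single_molecule normalization takes exactly one score map"
        )
    values = [s for m in scoremaps for s in m.scores.values()]
    if not values:
        raise NormalizationError("score maps contain no bonds")
    return NormalizationContext(mode=mode, s_min=min(values), s_max=max(values))


def normalize(score: float, ctx: NormalizationContext) -> float:
    """Affine map of a score to [0,1]; degenerate contexts map to 0.5.

    Scores outside the context range (possible for external compounds under
    a full_set context) are clamped and logged.
    """
    if ctx.s_max == ctx.s_min:
        return 0.5
    nu = (score - ctx.s_min) / (ctx.s_max - ctx.s_min)
    if nu < 0.0 or nu > 1.0:
        logger.info("score %g outside context [%g, %g]; clamped", score, ctx.s_min, ctx.s_max)
        nu = min(1.0, max(0.0, nu))
    return nu


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _mix(a: tuple[int, int, int], b: tuple[int, int, int], t: float) -> tuple[int, int, int]:
    return tuple(_round_half_up(ca + (cb - ca) * t) for ca, cb in zip(a, b))  # type: ignore[return-value]


def score_to_color(nu: float, gradient: Gradient = DEFAULT_GRADIENT) -> tuple[int, int, int]:
    """Two sub-gradients: negative->mid for nu <= 0.5, mid->positive above.

    Both branches yield the mid color exactly at nu = 0.5, so the combined
    map is continuous.
    """
    if not 0.0 <= nu <= 1.0:
        raise GradientRangeError(f"normalized score {nu} outside [0,1]; normalize first")
    if nu <= 0.5:
        return _mix(gradient.negative_color, gradient.mid_color, 2.0 * nu)
    return _mix(gradient.mid_color, gradient.positive_color, 2.0 * nu - 1.0)


def color_molecule(
    model: LinearModel,
    fp: ProvenancedFingerprint,
    mode: str = "single_molecule",
    training_scoremaps: Optional[Sequence[BondScoreMap]] = None,
    size_normalize: bool = False,
    gradient: Gradient = DEFAULT_GRADIENT,
) -> BondColoring:
    """bond_scores -> normalize -> score_to_color for every bond."""
    smap = bond_scores(model, fp, size_normalize=size_normalize)
    if not smap.scores:  # single-atom molecule: nothing to color
        return BondColoring(molecule=fp.molecule, entries={})
    if mode == "full_set":
        if not training_scoremaps:
            raise NormalizationError(
                "full_set normalization requires score maps for the whole "
                "training data set"
            )
        ctx = normalization_context("full_set", list(training_scoremaps) + [smap])
    elif mode == "single_molecule":
        ctx = normalization_context("single_molecule", [smap])
    else:
        raise NormalizationError(f"unknown mode {mode!r}")
    entries = {}
    for b, raw in smap.scores.items():
        nu = normalize(raw, ctx)
        entries[b] = BondColor(raw=raw, nu=nu, rgb=score_to_color(nu, gradient))
    return BondColoring(molecule=fp.molecule, entries=entries)


def coloring_to_csv(path, colorings: Sequence[BondColoring]) -> None:
    import pandas as pd

    rows = [row for c in colorings for row in c.to_rows()]
    pd.DataFrame(
        rows, columns=["molecule", "bond_index", "raw_score", "normalized_score", "color"]
    ).to_csv(path, index=False)
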