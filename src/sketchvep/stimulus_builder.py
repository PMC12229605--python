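"""SNR-graded compound stimuli and the session trial schedule.

A compound stimulus is an arrangement of ten 0.3 deg feature glyphs
scattered without overlap inside a 3 deg-diameter region.  Its "SNR" is
the percentage of glyphs drawn from the optimal feature set (0, 30, 60
or 100%; e.g. SNR 30% = 3 optimal + 7 non-optimal glyphs).  Compounds
are flashed for 25 ms at 4 deg eccentricity, 25 deg above or 45 deg
below the horizontal meridian, on a gray background isoluminant with the
mean of the black (3 cd/m2) and white (90 cd/m2) feature pixels.

A session comprises 2280 trials in 6 equal blocks: 1920 single-stimulus
EEG trials (balanced over the four SNR levels and the two visual
fields) and 360 interleaved two-alternative forced-choice (2AFC) trials
pairing an SNR 0% compound against a higher-SNR one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .feature_model import FeatureSet, decode_patch

SNR_LEVELS = (0, 30, 60, 100)
N_GLYPHS = 10


@dataclass(frozen=True)
class DisplayGeometry:
    """Stimulus geometry in degrees of visual angle and luminances in cd/m2."""

    deg_per_px_render: float = 0.3 / 9  # one glyph = 0.3 deg = 9 px
    glyph_deg: float = 0.3
    compound_radius_deg: float = 1.5
    min_distance_deg: float = 0.3
    eccentricity_deg: float = 4.0
    upper_polar_deg: float = 25.0
    lower_polar_deg: float = -45.0
    black_cd: float = 3.0
    white_cd: float = 90.0
    background_cd: float = 44.0

    def __post_init__(self) -> None:
        if self.glyph_deg > 2 * self.compound_radius_deg:
            raise ValueError("glyph does not fit inside the compound region")
        if min(self.black_cd, self.white_cd, self.background_cd) <= 0:
            raise ValueError("luminances must be positive")


@dataclass(frozen=True)
class Placement:
    """One glyph of a compound: pattern id, source set, center in degrees."""

    pattern_id: int
    source: Literal["optimal", "non_optimal"]
    x_deg: float
    y_deg: float


@dataclass
class CompoundStimulus:
    """Ten placed feature glyphs with an SNR label.

    Centers are in degrees relative to the compound center; ``rendered``
    holds the luminance image once :func:`render_stimulus` has run.
    """

    snr: int
    placements: list[Placement]
    rendered: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.snr not in SNR_LEVELS:
            raise ValueError(f"snr must be one of {SNR_LEVELS}, got {self.snr}")
        if len(self.placements) != N_GLYPHS:
            raise ValueError(f"expected {N_GLYPHS} placements")

    @property
    def n_optimal(self) -> int:
        return sum(1 for p in self.placements if p.source == "optimal")

    def min_pairwise_distance(self) -> float:
        xy = np.array([[p.x_deg, p.y_deg] for p in self.placements])
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        return float(d[np.triu_indices(N_GLYPHS, 1)].min())


def _sample_centers(
    rng: np.random.Generator,
    geometry: DisplayGeometry,
    n: int = N_GLYPHS,
    max_layouts: int = 100,
    max_attempts_per_point: int = 200,
) -> np.ndarray:
    """Dart-throwing placement of n glyph centers.

    Centers are uniform over the disk in which a glyph (a square of side
    ``glyph_deg``) stays fully inside the compound region; points closer
    than ``min_distance_deg`` to an accepted point are rejected.  A stuck
    layout is restarted from scratch; repeated failure raises.
    """
    r_eff = geometry.compound_radius_deg - geometry.glyph_deg * np.sqrt(2) / 2
    if r_eff <= 0:
        raise ValueError("glyph too large for the compound region")
    min_d2 = geometry.min_distance_deg**2
    for _ in range(max_layouts):
        pts: list[np.ndarray] = []
        for _ in range(n):
            for _ in range(max_attempts_per_point):
                r = r_eff * np.sqrt(rng.random())
                theta = rng.uniform(0, 2 * np.pi)
                cand = np.array([r * np.cos(theta), r * np.sin(theta)])
                if all(np.sum((cand - p) ** 2) >= min_d2 for p in pts):
                    pts.append(cand)
                    break
            else:
                break  # layout stuck; restart
        if len(pts) == n:
            return np.array(pts)
    raise RuntimeError(f"could not place {n} glyphs in {max_layouts} layouts")


def compose_compound(
    optimal: FeatureSet,
    nonoptimal: FeatureSet,
    snr: int,
    rng: np.random.Generator,
    geometry: DisplayGeometry = DisplayGeometry(),
) -> CompoundStimulus:
    """Draw a compound of snr/10 optimal and the rest non-optimal glyphs.

    Pattern ids are drawn with replacement from each set, positions by
    rejection sampling under the minimum-distance and containment
    constraints.
    """
    if snr not in SNR_LEVELS:
        raise ValueError(f"snr must be one of {SNR_LEVELS}, got {snr}")
    if len(optimal) == 0 or len(nonoptimal) == 0:
        raise ValueError("both feature sets must be non-empty")
    n_opt = snr // 10
    ids = [int(rng.choice(optimal.members)) for _ in range(n_opt)]
    ids += [int(rng.choice(nonoptimal.members)) for _ in range(N_GLYPHS - n_opt)]
    sources = ["optimal"] * n_opt + ["non_optimal"] * (N_GLYPHS - n_opt)
    centers = _sample_centers(rng, geometry)
    order = rng.permutation(N_GLYPHS)  # decouple position from source
    placements = [
        Placement(ids[i], sources[i], float(centers[j, 0]), float(centers[j, 1]))
        for i, j in enumerate(order)
    ]
    return CompoundStimulus(snr=snr, placements=placements)


def render_stimulus(
    compound: CompoundStimulus | Sequence[Placement],
    geometry: DisplayGeometry = DisplayGeometry(),
    canvas_px: int = 99,
    upsample: int = 3,
) -> np.ndarray:
    """Render a compound to a luminance image in cd/m2.

    The canvas is filled with the background gray; each glyph is its 3x3
    pattern upsampled to 9x9 px with black -> 3 and white -> 90 cd/m2,
    centered at the placement coordinates rounded to the nearest pixel.
    A bare sequence of placements (any length, including empty) is
    accepted as a test hook.
    """
    placements = (compound.placements if isinstance(compound, CompoundStimulus)
                  else list(compound))
    glyph_px = 3 * upsample
    img = np.full((canvas_px, canvas_px), geometry.background_cd)
    scale = 1.0 / geometry.deg_per_px_render
    c = canvas_px / 2.0
    for p in placements:
        # row axis points down; +y (up in the visual field) decreases row
        col0 = int(round(c + p.x_deg * scale - glyph_px / 2))
        row0 = int(round(c - p.y_deg * scale - glyph_px / 2))
        if (
            row0 < 0
            or col0 < 0
            or row0 + glyph_px > canvas_px
            or col0 + glyph_px > canvas_px
        ):
            raise ValueError("glyph clipped by canvas; increase canvas_px")
        patch = np.kron(decode_patch(p.pattern_id), np.ones((upsample, upsample)))
        img[row0 : row0 + glyph_px, col0 : col0 + glyph_px] = np.where(
            patch > 0, geometry.white_cd, geometry.black_cd
        )
    if isinstance(compound, CompoundStimulus):
        compound.rendered = img
    return img


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleConfig:
    """Trial counts and timing of one session.

    Defaults give the full design: 2280 trials in 6 equal blocks, of
    which 1920 are single-stimulus trials (240 per SNR x field cell) and
    360 are 2AFC trials.  All per-block cell counts must divide evenly,
    so scaled-down sessions keep the same balance.
    """

    n_blocks: int = 6
    singles_per_snr_field: int = 240  # per SNR x {upper, lower}, whole session
    n_afc: int = 360
    isi_range_ms: tuple[float, float] = (700.0, 800.0)
    single_duration_ms: float = 25.0
    afc_duration_ms: float = 24.0

    @property
    def n_single(self) -> int:
        return self.singles_per_snr_field * 2 * len(SNR_LEVELS)

    @property
    def n_trials(self) -> int:
        return self.n_single + self.n_afc


@dataclass
class TrialSchedule:
    """Ordered trial list for one session.

    ``trials`` is a DataFrame with one row per trial: index, block, kind
    (single/afc), field (upper/lower/both), snr (single trials), the 2AFC
    high-SNR level and its field, isi_ms, duration_ms and a per-trial rng
    seed.
    """

    trials: pd.DataFrame
    config: ScheduleConfig = field(default_factory=ScheduleConfig)

    def __len__(self) -> int:
        return len(self.trials)

    def to_tsv(self, path: str | Path) -> None:
        self.trials.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, config: ScheduleConfig | None = None) -> "TrialSchedule":
        df = pd.read_csv(path, sep="\t")
        df["snr"] = df["snr"].astype("Int64")
        df["afc_high_snr"] = df["afc_high_snr"].astype("Int64")
        return cls(df, config or ScheduleConfig())


def build_schedule(
    config: ScheduleConfig = ScheduleConfig(),
    rng: np.random.Generator | None = None,
) -> TrialSchedule:
    """Build a randomized, block-balanced trial schedule.

    Every block holds the same number of trials from each SNR x field
    cell and of 2AFC trials, shuffled within the block.  2AFC trials pair
    an SNR 0% compound with one drawn uniformly from {30, 60, 100}%, with
    the up/down assignment of the higher-SNR member randomized.  ISIs are
    uniform on ``isi_range_ms``.
    """
    rng = np.random.default_rng() if rng is None else rng
    per_block_cell, rem1 = divmod(config.singles_per_snr_field, config.n_blocks)
    afc_per_block, rem2 = divmod(config.n_afc, config.n_blocks)
    if rem1 or rem2:
        raise ValueError(
            f"counts do not balance over {config.n_blocks} blocks "
            f"(remainders: singles_per_snr_field {rem1}, afc {rem2})"
        )
    rows = []
    for block in range(1, config.n_blocks + 1):
        block_rows = []
        for snr in SNR_LEVELS:
            for fld in ("upper", "lower"):
                for _ in range(per_block_cell):
                    block_rows.append(
                        dict(kind="single", field=fld, snr=snr,
                             afc_high_snr=None, afc_high_field=None,
                             duration_ms=config.single_duration_ms)
                    )
        for _ in range(afc_per_block):
            high = int(rng.choice([30, 60, 100]))
            high_field = str(rng.choice(["upper", "lower"]))
            block_rows.append(
                dict(kind="afc", field="both", snr=None,
                     afc_high_snr=high, afc_high_field=high_field,
                     duration_ms=config.afc_duration_ms)
            )
        order = rng.permutation(len(block_rows))
        for i in order:
            r = dict(block_rows[i])
            r["block"] = block
            rows.append(r)
    df = pd.DataFrame(rows)
    df.insert(0, "index", np.arange(len(df)))
    df["isi_ms"] = rng.uniform(*config.isi_range_ms, size=len(df))
    df["trial_seed"] = rng.integers(0, 2**31 - 1, size=len(df))
    df["snr"] = df["snr"].astype("Int64")
    df["afc_high_snr"] = df["afc_high_snr"].astype("Int64")
    cols = ["index", "block", "kind", "field", "snr", "afc_high_snr",
            "afc_high_field", "isi_ms", "duration_ms", "trial_seed"]
    return TrialSchedule(df[cols], config)


def scaled_schedule_config(factor: int) -> ScheduleConfig:
    """A schedule shrunk by an integer factor, keeping block balance.

    ``factor`` must divide the default per-block cell counts (40 singles
    per SNR x field, 60 afc); valid factors include 2, 4, 5, 10, 20.
    """
    base = ScheduleConfig()
    return replace(
        base,
        singles_per_snr_field=base.singles_per_snr_field // factor,
        n_afc=base.n_afc // factor,
    )
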