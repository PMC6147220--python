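"""Factorial trial tables for the three experiments.

Three designs are generated, with the single sounds pseudo-randomly
interleaved among the doubles under a seed:

* ``localization`` — 720 double-sound trials (5 level differences x 3
  modulation frequencies x 24 speaker-pair configurations x 2
  target/distractor assignments) plus 119 single-sound trials (7 sound kinds
  x 17 unique elevations), 839 in total.
* ``discrim_freq`` — 2AFC up/down identification: 120 doubles (2 AM
  positions x 3 modulation frequencies x 20 repeats) + 60 singles.
* ``discrim_phase`` — 480 trials at 5 Hz: 160 singles (8 phases x 2
  positions x 10) + 320 doubles (8 phases x 2 positions x 2 modulated-sound
  kinds x 10).

The 24 elevation pairs live in a versioned config file
(``data/double_sound_pairs.csv``); their separations tile {15, 30, 45, 60,
75} degrees and they use exactly 17 unique elevations between -45 and +75 on
the midsagittal plane (azimuth 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DELTA_L_DB",
    "MODULATION_FREQS_HZ",
    "LEVELS_DBA",
    "SINGLE_SOUND_KINDS",
    "TrialTable",
    "load_speaker_pairs",
    "single_sound_elevations",
    "build_localization_trials",
    "build_discrim_freq_trials",
    "build_discrim_phase_trials",
    "interleave",
]

DELTA_L_DB = (-10.0, -5.0, 0.0, 5.0, 10.0)
MODULATION_FREQS_HZ = (5.0, 120.0, 2000.0)
LEVELS_DBA = (45.0, 50.0, 55.0, 60.0, 65.0)
SINGLE_SOUND_KINDS = ("GWN", "AM5", "AM120", "AM2000", "G5", "G120", "G2000")

#: Column order of a trial table.
TRIAL_COLUMNS = [
    "trial",
    "trial_type",
    "target_el",
    "distractor_el",
    "delta_l_db",
    "fm_hz",
    "phase_rad",
    "base_level_dba",
    "target_level_dba",
    "distractor_level_dba",
    "sound_kind",
    "duration_ms",
]


@dataclass
class TrialTable:
    """An ordered trial list with its design name and interleaving seed."""

    trials: pd.DataFrame
    seed: int
    design_name: str

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def doubles(self) -> pd.DataFrame:
        return self.trials[self.trials.trial_type == "double"]

    @property
    def singles(self) -> pd.DataFrame:
        return self.trials[self.trials.trial_type == "single"]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# design_name={self.design_name}\n")
            fh.write(f"# seed={self.seed}\n")
            self.trials.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        path = Path(path)
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
        df = pd.read_csv(path, comment="#")
        return cls(df, seed=int(meta.get("seed", 0)), design_name=meta.get("design_name", ""))


def load_speaker_pairs() -> pd.DataFrame:
    """The 24 double-sound elevation pairs (low_el, high_el, separation_deg)."""
    with resources.files("samloc.data").joinpath("double_sound_pairs.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def single_sound_elevations() -> np.ndarray:
    """The 17 unique elevations occurring in the double-sound pairs."""
    pairs = load_speaker_pairs()
    return np.unique(np.concatenate([pairs.low_el.values, pairs.high_el.values])).astype(float)


def _kind_fm(kind: str) -> float:
    """Modulation frequency implied by a single-sound kind label (NaN for GWN)."""
    digits = "".join(c for c in kind if c.isdigit())
    return float(digits) if digits else np.nan


def _finish(rows: list[dict], seed: int, design_name: str) -> TrialTable:
    df = pd.DataFrame(rows)
    df["trial"] = np.arange(len(df))
    df = df[TRIAL_COLUMNS]
    return interleave(TrialTable(df, seed=seed, design_name=design_name), seed)


def build_localization_trials(seed: int = 0) -> TrialTable:
    """The open-loop localization design: 720 doubles + 119 singles = 839.

    Doubles cross level difference (AM - GWN, dB) x modulation frequency x
    24 elevation pairs x which of the pair holds the AM target.  Per trial
    the AM level is drawn uniformly from the calibrated levels (45-65 dBA)
    that keep both sounds inside the calibrated range at the required
    difference.  Singles present each of the 7 sound kinds at each of the 17
    elevations at 55 dBA.
    """
    rng = np.random.default_rng(seed)
    pairs = load_speaker_pairs()
    rows: list[dict] = []
    for dl in DELTA_L_DB:
        feasible = [l for l in LEVELS_DBA if 45.0 <= l - dl <= 65.0]
        for fm in MODULATION_FREQS_HZ:
            for _, pr in pairs.iterrows():
                for target_high in (False, True):
                    t_el, d_el = (
                        (pr.high_el, pr.low_el) if target_high else (pr.low_el, pr.high_el)
                    )
                    am_level = float(rng.choice(feasible))
                    gwn_level = am_level - dl
                    rows.append(
                        dict(
                            trial_type="double",
                            target_el=float(t_el),
                            distractor_el=float(d_el),
                            delta_l_db=dl,
                            fm_hz=fm,
                            phase_rad=0.0,
                            base_level_dba=(am_level + gwn_level) / 2.0,
                            target_level_dba=am_level,
                            distractor_level_dba=gwn_level,
                            sound_kind=f"AM{int(fm)}",
                            duration_ms=150.0,
                        )
                    )
    for kind in SINGLE_SOUND_KINDS:
        for el in single_sound_elevations():
            rows.append(
                dict(
                    trial_type="single",
                    target_el=float(el),
                    distractor_el=np.nan,
                    delta_l_db=np.nan,
                    fm_hz=_kind_fm(kind),
                    phase_rad=0.0,
                    base_level_dba=55.0,
                    target_level_dba=55.0,
                    distractor_level_dba=np.nan,
                    sound_kind=kind,
                    duration_ms=150.0,
                )
            )
    return _finish(rows, seed, "localization")


def build_discrim_freq_trials(seed: int = 0) -> TrialTable:
    """Frequency-discrimination 2AFC: 120 doubles + 60 singles, all 55 dBA.

    Doubles place the AM target (phase 0) at +20 or -20 deg with the flat
    GWN distractor at the opposite position, 20 repeats per (position, fm)
    cell, 400 ms duration.  Singles are the AM sounds alone, balanced over
    fm (2 positions x 3 fm x 10 repeats).
    """
    rows: list[dict] = []
    for fm in MODULATION_FREQS_HZ:
        for t_el in (20.0, -20.0):
            for _ in range(20):
                rows.append(
                    dict(
                        trial_type="double",
                        target_el=t_el,
                        distractor_el=-t_el,
                        delta_l_db=0.0,
                        fm_hz=fm,
                        phase_rad=0.0,
                        base_level_dba=55.0,
                        target_level_dba=55.0,
                        distractor_level_dba=55.0,
                        sound_kind=f"AM{int(fm)}",
                        duration_ms=400.0,
                    )
                )
            for _ in range(10):
                rows.append(
                    dict(
                        trial_type="single",
                        target_el=t_el,
                        distractor_el=np.nan,
                        delta_l_db=np.nan,
                        fm_hz=fm,
                        phase_rad=0.0,
                        base_level_dba=55.0,
                        target_level_dba=55.0,
                        distractor_level_dba=np.nan,
                        sound_kind=f"AM{int(fm)}",
                        duration_ms=400.0,
                    )
                )
    return _finish(rows, seed, "discrim_freq")


def build_discrim_phase_trials(seed: int = 0) -> TrialTable:
    """Phase-discrimination 2AFC at 5 Hz: 160 singles + 320 doubles = 480.

    Factors: 8 modulation phases (0..7*pi/4) x 2 AM positions (+/-20 deg) x,
    for doubles, 2 modulated-sound kinds (pure AM vs superimposed GWN+AM
    composite) x 10 repeats.  All sounds 400 ms at 55 dBA.
    """
    phases = np.arange(8) * np.pi / 4
    rows: list[dict] = []
    for phi in phases:
        for t_el in (20.0, -20.0):
            for _ in range(10):
                rows.append(
                    dict(
                        trial_type="single",
                        target_el=t_el,
                        distractor_el=np.nan,
                        delta_l_db=np.nan,
                        fm_hz=5.0,
                        phase_rad=float(phi),
                        base_level_dba=55.0,
                        target_level_dba=55.0,
                        distractor_level_dba=np.nan,
                        sound_kind="AM5",
                        duration_ms=400.0,
                    )
                )
            for kind in ("AM5", "G5"):
                for _ in range(10):
                    rows.append(
                        dict(
                            trial_type="double",
                            target_el=t_el,
                            distractor_el=-t_el,
                            delta_l_db=0.0,
                            fm_hz=5.0,
                            phase_rad=float(phi),
                            base_level_dba=55.0,
                            target_level_dba=55.0,
                            distractor_level_dba=55.0,
                            sound_kind=kind,
                            duration_ms=400.0,
                        )
                    )
    return _finish(rows, seed, "discrim_phase")


def interleave(table: TrialTable, seed: int) -> TrialTable:
    """Pseudo-randomly permute the trial order, reproducibly from ``seed``.

    The trial multiset (including the original ``trial`` ids) is preserved;
    only the presentation order changes.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(table.trials))
    df = table.trials.iloc[order].reset_index(drop=True)
    return TrialTable(df, seed=seed, design_name=table.design_name)
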