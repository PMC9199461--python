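"""Synthetic experiment generator.

Generates complete observation tables — leaf/bud counts, per-tree average
SPAD chlorophyll, and leaf-level net photosynthesis — for the 81-tree
removal experiment, with configurable, known-truth treatment effects so
that every downstream stage can be validated by parameter recovery.

Data-generating model
---------------------
* Whole-plant senescence of tree *t* is governed by a latent midpoint

  ``m_t = spad_midpoint + delay_leaf * leaf_pct + delay_bud * bud_pct
          + b_block + b_tree``

  where the block and tree intercepts are Gaussian.  Average SPAD
  follows a falling logistic with midpoint ``m_t``; leaf drop follows a
  logistic lagged by ``count_decline_lag`` days.  Because every curve of
  a tree shifts rigidly with ``m_t``, the configured per-percent delay
  propagates one-to-one into the day of 50 % senescence.
* Leaf counts start from a leaf-out-group-dependent baseline, are cut by
  the treatment percentage at the two removal events (rounded, ties to
  even), regrow between events at ``regrowth_gain`` of the removed count
  per day (Poisson when noise is on), and decline with the leaf-drop
  logistic in autumn.  Bud counts are cut once and regrow similarly;
  buds do not senesce.
* Net photosynthesis declines along a seasonal logistic; its amplitude
  scales linearly along the leaf-removal gradient so that the noise-free
  area under the curve of a 75 % tree exceeds the control's by exactly
  ``true_photo_effect_pct`` percent.  A configurable fraction of records
  carries an implausible covariate (negative stomatal conductance)
  and/or a leaf too small to fill the chamber, to exercise QC.

All randomness is derived from ``config.seed`` through independent,
purpose-keyed streams, so observation tables are bit-identical for
identical configurations and each tree can be simulated in isolation.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .design import TreeRecord, design_frame, design_from_frame

__all__ = [
    "simulate_counts",
    "simulate_chlorophyll",
    "simulate_photosynthesis",
    "simulate_experiment",
    "write_dataset",
    "read_dataset",
]

COUNT_COLUMNS = ["tree_id", "doy", "organ", "count", "event_phase"]
SPAD_COLUMNS = ["tree_id", "doy", "avg_spad"]
PHOTO_COLUMNS = ["tree_id", "doy", "a_net_umol_m2_s", "covered_fraction", "gsw", "leafless_flag"]

# stream keys: independent RNG sub-streams per (seed, purpose, unit)
_S_BLOCK_MID, _S_BLOCK_PHOTO = 101, 102
_S_TREE_LATENT = 201
_S_EVENT, _S_COUNT_NOISE, _S_SPAD_NOISE, _S_PHOTO = 300, 301, 302, 303


def _rng(config: SimulationConfig, stream: int, unit: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, unit])


def _round(x: float) -> int:
    """Round half to even, returning a Python int."""
    return int(np.round(x))


def _logistic_decline(d, midpoint: float, scale: float):
    """Falling logistic: 1 at d << midpoint, 1/2 at the midpoint, -> 0."""
    return 1.0 / (1.0 + np.exp((np.asarray(d, dtype=float) - midpoint) / scale))


def _tree_num(tree: TreeRecord) -> int:
    return int(tree.tree_id.lstrip("T"))


def _tree_latents(tree: TreeRecord, config: SimulationConfig) -> dict:
    """Latent quantities shared across a tree's observation streams."""
    rng = _rng(config, _S_TREE_LATENT, _tree_num(tree))
    b_mid = _rng(config, _S_BLOCK_MID, tree.block_id).normal(0.0, config.block_midpoint_sd)
    b_photo = _rng(config, _S_BLOCK_PHOTO, tree.block_id).normal(0.0, config.photo_block_sd)
    t_mid = rng.normal(0.0, config.tree_midpoint_sd)
    t_photo = rng.normal(0.0, config.photo_tree_sd)
    leafout_factor = 1.0 + config.leafout_count_effect * (3 - tree.leaf_out_group)
    leaf0 = max(5, _round(rng.normal(config.leaf0_mean * leafout_factor, config.leaf0_sd)))
    bud0 = max(3, _round(rng.normal(config.bud0_mean * leafout_factor, config.bud0_sd)))
    midpoint = (
        config.spad_midpoint_doy
        + config.true_senescence_delay_per_pct * tree.leaf_removal_pct
        + config.true_bud_delay_per_pct * tree.bud_removal_pct
        + b_mid
        + t_mid
    )
    photo_amp = (
        config.photo_amplitude
        * (1.0 + config.true_photo_effect_pct / 100.0 * tree.leaf_removal_pct / 75.0)
        * max(0.05, 1.0 + t_photo)
        * max(0.05, 1.0 + b_photo)
    )
    return {
        "midpoint": midpoint,
        "photo_amp": photo_amp,
        "leaf0": leaf0,
        "bud0": bud0,
    }


def _leaf_survival(d, midpoint: float, config: SimulationConfig):
    return _logistic_decline(d, midpoint + config.count_decline_lag, config.count_decline_steepness)


def _leaf_process(tree: TreeRecord, config: SimulationConfig) -> dict:
    """Leaf-count trajectory of one tree, including removal-event censuses.

    Event observations are exact censuses: the post-removal count is
    ``round((1 - pct/100) * observed pre count)`` by construction, and
    feeds forward into the subsequent trajectory.
    """
    lat = _tree_latents(tree, config)
    rng = _rng(config, _S_EVENT, _tree_num(tree))
    p = tree.leaf_removal_pct / 100.0
    e1, e2 = config.leaf_removal_1_doy, config.leaf_removal_2_doy
    m = lat["midpoint"]
    noisy = config.count_noise_cv > 0

    pre1 = lat["leaf0"]
    post1 = _round((1.0 - p) * pre1)
    removed1 = pre1 - post1
    cap1 = _round(1.5 * pre1)

    def regrown(days: float) -> int:
        mean = config.regrowth_gain * removed1 * days
        return int(rng.poisson(mean)) if noisy else _round(mean)

    pre2 = min(post1 + regrown(e2 - e1), cap1)
    pre2 = _round(pre2 * float(_leaf_survival(e2, m, config) / _leaf_survival(e1, m, config)))
    post2 = _round((1.0 - p) * pre2)

    def expectation(d: float) -> float:
        """Noise-free expected leaf count at day *d* (scheduled dates)."""
        if d <= e1:
            return pre1 * float(_leaf_survival(d, m, config) / _leaf_survival(e1, m, config))
        if d <= e2:
            base = min(post1 + config.regrowth_gain * removed1 * (d - e1), cap1)
            return base * float(_leaf_survival(d, m, config) / _leaf_survival(e1, m, config))
        return post2 * float(_leaf_survival(d, m, config) / _leaf_survival(e2, m, config))

    return {
        "pre1": pre1, "post1": post1, "pre2": pre2, "post2": post2,
        "midpoint": m, "expectation": expectation, "latents": lat,
    }


def _count_records(tree: TreeRecord, config: SimulationConfig) -> list[tuple]:
    proc = _leaf_process(tree, config)
    lat = proc["latents"]
    rng = _rng(config, _S_COUNT_NOISE, _tree_num(tree))
    cv = config.count_noise_cv
    rows: list[tuple] = []

    def observe(expected: float) -> int:
        # censuses miscount a small fraction of organs, not a fixed number
        factor = 1.0 + rng.normal(0.0, cv) if cv > 0 else 1.0
        return max(0, _round(expected * factor))

    # leaf organ: two removal events with paired pre/post censuses
    e1, e2 = config.leaf_removal_1_doy, config.leaf_removal_2_doy
    rows.append((tree.tree_id, e1, "leaf", proc["pre1"], "pre"))
    rows.append((tree.tree_id, e1, "leaf", proc["post1"], "post"))
    rows.append((tree.tree_id, e2, "leaf", proc["pre2"], "pre"))
    rows.append((tree.tree_id, e2, "leaf", proc["post2"], "post"))
    for d in config.counts_spad_doys:
        rows.append((tree.tree_id, d, "leaf", observe(proc["expectation"](d)), "none"))

    # bud organ: single removal, regrowth, no senescence
    b = tree.bud_removal_pct / 100.0
    eb = config.bud_removal_doy
    pre_b = lat["bud0"]
    post_b = _round((1.0 - b) * pre_b)
    removed_b = pre_b - post_b
    cap_b = _round(1.2 * pre_b)
    rows.append((tree.tree_id, eb, "bud", pre_b, "pre"))
    rows.append((tree.tree_id, eb, "bud", post_b, "post"))
    noisy = cv > 0

    def bud_expect(d: float) -> float:
        if d <= eb:
            return float(pre_b)
        mean = config.bud_regrowth_gain * removed_b * (d - eb)
        gain = rng.poisson(mean) if noisy else _round(mean)
        return float(min(post_b + gain, cap_b))

    for d in config.counts_spad_doys:
        rows.append((tree.tree_id, d, "bud", observe(bud_expect(d)), "none"))
    return rows


def simulate_counts(tree: TreeRecord, config: SimulationConfig) -> pd.DataFrame:
    """Dated leaf and bud counts for one tree.

    Returns one leaf and one bud count per scheduled count/SPAD day plus
    paired pre/post censuses on each removal day.  Counts are
    non-negative integers; immediately after a removal the removed
    organ's count equals ``round((1 - pct/100) * pre-removal count)``.
    """
    config.validate()
    return pd.DataFrame(_count_records(tree, config), columns=COUNT_COLUMNS)


def _spad_records(tree: TreeRecord, config: SimulationConfig) -> list[tuple]:
    lat = _tree_latents(tree, config)
    rng = _rng(config, _S_SPAD_NOISE, _tree_num(tree))
    sd = config.spad_noise_sd
    rows = []
    for d in config.counts_spad_doys:
        s = config.spad_plateau * float(_logistic_decline(d, lat["midpoint"], config.spad_steepness))
        if sd > 0:
            s += rng.normal(0.0, sd)
        rows.append((tree.tree_id, d, max(0.0, float(s))))
    return rows


def simulate_chlorophyll(tree: TreeRecord, config: SimulationConfig) -> pd.DataFrame:
    """Per-tree average SPAD on each scheduled count/SPAD day.

    SPAD falls along a logistic from its plateau toward zero; the
    midpoint carries the treatment delay and the tree/block intercepts,
    so the bud arm is a configurable null.
    """
    config.validate()
    return pd.DataFrame(_spad_records(tree, config), columns=SPAD_COLUMNS)


def _photo_records(tree: TreeRecord, config: SimulationConfig) -> list[tuple]:
    proc = _leaf_process(tree, config)
    lat = proc["latents"]
    rng = _rng(config, _S_PHOTO, _tree_num(tree))
    rows = []
    for first_doy in config.photosynthesis_doys:
        # measurements run over a few days; the flux refers to the
        # interval's canonical (first) day, the record keeps the actual day
        obs_doy = first_doy + int(rng.integers(0, 3))
        leafless = _round(proc["expectation"](first_doy)) < 1
        if leafless:
            rows.append((tree.tree_id, obs_doy, 0.0, 1.0, 0.0, True))
            continue
        a_leaf = lat["photo_amp"] * float(
            _logistic_decline(first_doy, config.photo_midpoint_doy, config.photo_steepness)
        )
        if config.photo_noise_sd > 0:
            a_leaf += rng.normal(0.0, config.photo_noise_sd)
        covered = 1.0
        if config.small_leaf_rate > 0 and rng.random() < config.small_leaf_rate:
            covered = float(rng.uniform(0.4, 0.95))
        if config.qc_artifact_rate > 0 and rng.random() < config.qc_artifact_rate:
            gsw = -float(rng.uniform(0.005, 0.05))
        else:
            gsw = float(rng.uniform(0.05, 0.30))
        # the instrument sees the chamber-average flux, diluted by the
        # fraction of the chamber the leaf actually covers
        rows.append((tree.tree_id, obs_doy, float(a_leaf * covered), covered, gsw, False))
    return rows


def simulate_photosynthesis(tree: TreeRecord, config: SimulationConfig) -> pd.DataFrame:
    """Six dated leaf-level net photosynthesis records for one tree.

    The recorded flux is on the chamber basis (true leaf-area flux times
    ``covered_fraction``); QC's leaf-area correction restores the
    per-leaf-area value.  Trees simulated leafless get ``a_net = 0`` and
    the leafless flag.
    """
    config.validate()
    return pd.DataFrame(_photo_records(tree, config), columns=PHOTO_COLUMNS)


def simulate_experiment(
    design: Sequence[TreeRecord], config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Simulate all observation tables for a full design.

    Returns ``{"trees": ..., "counts": ..., "spad": ..., "photosynthesis": ...}``.
    """
    config.validate()
    if len(design) == 0:
        raise ConfigError("design contains no trees")
    counts: list[tuple] = []
    spad: list[tuple] = []
    photo: list[tuple] = []
    for tree in design:
        counts.extend(_count_records(tree, config))
        spad.extend(_spad_records(tree, config))
        photo.extend(_photo_records(tree, config))
    return {
        "trees": design_frame(list(design)),
        "counts": pd.DataFrame(counts, columns=COUNT_COLUMNS),
        "spad": pd.DataFrame(spad, columns=SPAD_COLUMNS),
        "photosynthesis": pd.DataFrame(photo, columns=PHOTO_COLUMNS),
    }


# ---------------------------------------------------------------------------
# CSV round trip

_FILES = ("trees", "counts", "spad", "photosynthesis")


def write_dataset(
    tables: dict[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    year: int = 2020,
    overwrite: bool = False,
) -> dict[str, str]:
    """Write the four observation tables as commented CSV files.

    Refuses to overwrite existing files unless ``overwrite=True``.
    Returns the written paths keyed by table name.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name in _FILES:
        if name not in tables:
            raise KeyError(f"missing table '{name}'")
        path = os.path.join(out_dir, f"{name}.csv")
        if os.path.exists(path) and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
        with open(path, "w", newline="") as fh:
            fh.write(f"# year={year}\n")
            tables[name].to_csv(fh, index=False)
        paths[name] = path
    return paths


def read_dataset(in_dir: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Read back a dataset written by :func:`write_dataset`."""
    tables = {}
    for name in _FILES:
        path = os.path.join(in_dir, f"{name}.csv")
        tables[name] = pd.read_csv(path, comment="#")
    if "leafless_flag" in tables["photosynthesis"].columns:
        tables["photosynthesis"]["leafless_flag"] = tables["photosynthesis"][
            "leafless_flag"
        ].astype(bool)
    return tables


def read_design(in_dir: str | os.PathLike) -> list[TreeRecord]:
    """Read ``trees.csv`` back into design records."""
    df = pd.read_csv(os.path.join(in_dir, "trees.csv"), comment="#")
    return design_from_frame(df)
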