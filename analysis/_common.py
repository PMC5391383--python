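"""Shared setup for the numbered analysis scripts.

Every script rebuilds its inputs deterministically from the run seed (the
generators are pure functions of seed + spec), so the stages can be run
independently and in any order; files written by earlier stages are for
inspection, not required inputs.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from tailscope.synthdata import (
    PeptideGenSpec,
    gen_active_inactive_pair,
    gen_peptide_trajectory,
)

N_FRAMES = 2000
DEFAULT_SEED = 20000


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--n-frames", type=int, default=N_FRAMES)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    return args


def stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    return {"unmodified": int(state[0]), "pair": int(state[1]), "poses": int(state[2])}


def build_ensembles(seed: int, n_frames: int):
    """The three study ensembles: unmodified, active-like, inactive-like."""
    s = stage_seeds(seed)
    unmod = gen_peptide_trajectory(
        PeptideGenSpec(seed=s["unmodified"], n_frames=n_frames, label="unmodified")
    )
    active, inactive = gen_active_inactive_pair(n_frames=n_frames, seed=s["pair"])
    return {"unmodified": unmod, "active": active, "inactive": inactive}
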