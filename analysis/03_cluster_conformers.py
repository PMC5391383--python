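#!/usr/bin/env python
"""Conformational clustering: full tail at 13 Å, then 15-residue tip re-clustering.

Subsamples each ensemble (the all-vs-all RMSD matrix is quadratic in frames),
clusters by single linkage, and writes per-frame assignments plus the medoid
("median") structure of the most populated cluster for every ensemble and
selection.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import build_ensembles, parse_args

from tailscope.confcluster import representative, rmsd_matrix, single_linkage
from tailscope.structio import Trajectory, write_structure

CUTOFF = 13.0  # Å
TIP_LEN = 15
MAX_FRAMES = 80


def main():
    args = parse_args(__doc__)
    out = args.outdir / "clusters"
    out.mkdir(exist_ok=True)
    for name, traj in build_ensembles(args.seed, args.n_frames).items():
        stride = max(1, traj.n_frames // MAX_FRAMES)
        sub = Trajectory(traj.topology, traj.frames[::stride], traj.dt * stride)
        for tag, sel in (("full", (1, 43)), ("tip", (1, TIP_LEN))):
            c = single_linkage(rmsd_matrix(sub, selection=sel), CUTOFF)
            c.to_frame().to_csv(out / f"{name}_{tag}_clusters.csv", index=False)
            rep = representative(sub, c, k=1)
            write_structure(out / f"{name}_{tag}_rep.pdb", rep)
            print(f"{name} [{tag}]: {c.n_clusters} cluster(s), "
                  f"populations {c.populations()[:5]}, medoid frame {c.medoids[0]}")


if __name__ == "__main__":
    main()
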