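#!/usr/bin/env python
"""Generate the synthetic H3 tail ensembles that stand in for the MD runs.

Writes one multi-model PDB per ensemble (subsampled for file size) plus a
manifest of the generator settings.  The unmodified ensemble carries the two
planted helices (tip T3-G12 at persistence 0.8, middle L20-A29 at 0.4); the
active/inactive pair carries the planted reach difference.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import build_ensembles, parse_args, stage_seeds

from tailscope.structio import Trajectory, write_trajectory


def main():
    args = parse_args(__doc__)
    out = args.outdir / "ensembles"
    out.mkdir(exist_ok=True)
    ensembles = build_ensembles(args.seed, args.n_frames)
    stride = max(1, args.n_frames // 100)  # keep the PDBs small
    manifest = {"seed": args.seed, "stage_seeds": stage_seeds(args.seed),
                "n_frames": args.n_frames, "pdb_stride": stride, "files": {}}
    for name, traj in ensembles.items():
        path = out / f"{name}.pdb"
        write_trajectory(path, Trajectory(traj.topology, traj.frames[::stride], traj.dt * stride))
        manifest["files"][name] = str(path)
        print(f"{name}: {traj.n_frames} frames generated, "
              f"{traj.n_frames // stride} written to {path}")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print(f"manifest -> {out / 'manifest.json'}")


if __name__ == "__main__":
    main()
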