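#!/usr/bin/env python
"""Generate the four synthetic receptor ensembles and their 10 ns poses.

One ensemble per system (FZD6 wild-type, SMO wild-type and the two 6.43
point mutants), each with the four-replica layout [500, 250, 250, 250] ns
at 100 ps/frame and the system's TM6 vertex-angle law. Writes the
one-frame-per-10-ns subsampled poses (126 per system) as multi-model PDB
plus the BW residue map, the inputs of the downstream pocket and angle
analyses.
"""

from pathlib import Path

from classf import synthetic_data as syn
from classf.structure_io import Trajectory, write_multimodel_pdb

OUT = Path(__file__).resolve().parent.parent / "results" / "ensembles"
SYSTEMS = ("fzd6", "smo", "fzd6_P643F", "smo_F643P")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    helix = syn.HelixSpec()
    syn.helix_residue_map(helix).to_json(OUT / "map.json")
    for system in SYSTEMS:
        trajs = syn.generate_trajectory(
            helix, syn.kink_preset(system), syn.EnsembleSpec(seed=SEED)
        )
        frames, count = syn.subsample_frames(trajs, 10.0)
        stamped = [
            f.with_coords(f.coords, time_ps=i * 10_000.0) for i, f in enumerate(frames)
        ]
        path = OUT / f"{system}_poses.pdb"
        write_multimodel_pdb(
            Trajectory(stamped, replica_id=0, frame_interval_ps=10_000.0), path
        )
        print(f"{system}: {count} poses -> {path.name}")


if __name__ == "__main__":
    main()
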