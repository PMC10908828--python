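#!/usr/bin/env python
"""Worked examples on the deposited chaperone-complex structures.

These analyses reproduce the published comparison numbers for the
RAF1-HSP90-CDC37 closed state and the HSP90 semi-open dimers, but they
need structure files the user must download once (this package never
fetches remote data):

    8U1L.pdb   closed-state RAF1-HSP90-CDC37 complex
    8U1M.pdb   semi-open HSP90 dimer
    5FWK.pdb   CDK4-HSP90-CDC37 closed state (comparison)
    4IVG.pdb   TRAP1 dimer (comparison)
    hsp90.fasta  T. ni HSP90 plus human HSP90 alpha/beta sequences

Place them (legacy PDB format) in a directory and run:

    python scripts/deposited_examples.py --data-dir downloads/

Expected scales: protomer-asymmetry Ca RMSD of the closed state ~0.7 A;
closed vs 5FWK ~1.4 A; semi-open vs closed ~3.7 A; semi-open vs 4IVG
~2.7 A; luminal occupancy of the client segment ~15%; insect vs human
HSP90 ~82% identity / ~90% similarity.
"""

from __future__ import annotations

import argparse
import itertools
import json
from pathlib import Path

import numpy as np

from chapdyn.cavity import luminal_cavity, make_cavity_grids, occupancy_fraction
from chapdyn.comparative import global_align, protomer_asymmetry, superpose
from chapdyn.core_io import read_fasta, read_structure
from chapdyn.selection import apply_selection


def chain_pair_rmsd(struct_a, struct_b, chain_a, chain_b):
    """Alignment-guided Ca RMSD between one chain of each structure."""
    seq_a = struct_a.chain_sequence(chain_a)
    seq_b = struct_b.chain_sequence(chain_b)
    aln = global_align(seq_a, seq_b)
    return superpose(struct_a, struct_b, aln.correspondence,
                     chain_a=chain_a, chain_b=chain_b)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, required=True)
    ap.add_argument("--out", type=Path, default=Path("deposited_examples.json"))
    args = ap.parse_args()
    d = args.data_dir
    results: dict = {}

    closed_path = d / "8U1L.pdb"
    if closed_path.exists():
        closed, _ = read_structure(closed_path)
        sup, aln = protomer_asymmetry(closed, "A", "B")
        results["closed_protomer_rmsd_A"] = round(sup.rmsd, 2)

        # luminal cavity of the closed state: walls are the two HSP90
        # protomer chains; the client segment is the unfolded RAF1
        # N-lobe beta5 strand threaded through the lumen (residues 418-426)
        walls = apply_selection(closed, "chain A or chain B")
        client = apply_selection(closed, "chain C and resseq 418-426")
        if client.size:
            grids = make_cavity_grids(closed, walls, 0.5, 1.4)
            res = luminal_cavity(*grids, closed.coords[client].mean(axis=0))
            occupancy_fraction(res, closed, client)
            results["closed_cavity_volume_A3"] = round(res.cavity_volume, 1)
            results["closed_occupancy_pct"] = round(100 * res.occupancy, 1)

    comparisons = [
        ("closed_vs_5FWK_rmsd_A", "8U1L.pdb", "5FWK.pdb"),
        ("semiopen_vs_closed_rmsd_A", "8U1M.pdb", "8U1L.pdb"),
        ("semiopen_vs_4IVG_rmsd_A", "8U1M.pdb", "4IVG.pdb"),
    ]
    for key, fa, fb in comparisons:
        pa, pb = d / fa, d / fb
        if pa.exists() and pb.exists():
            sa, _ = read_structure(pa)
            sb, _ = read_structure(pb)
            sup = chain_pair_rmsd(sa, sb, sa.chains[0], sb.chains[0])
            results[key] = round(sup.rmsd, 2)

    fasta = d / "hsp90.fasta"
    if fasta.exists():
        seqs = read_fasta(fasta)
        for (na, sa), (nb, sb) in itertools.combinations(seqs.items(), 2):
            aln = global_align(sa, sb)
            results[f"identity_pct_{na}_vs_{nb}"] = round(aln.percent_identity, 1)
            results[f"similarity_pct_{na}_vs_{nb}"] = round(aln.percent_similarity, 1)

    if not results:
        raise SystemExit(f"no input structures found under {d}; see the module docstring")
    args.out.write_text(json.dumps(results, indent=2, sort_keys=True))
    print(json.dumps(results, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
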