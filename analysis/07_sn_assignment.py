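#!/usr/bin/env python
"""Lysophospholipid sn-position assignment demonstration: simulate
negative-mode MS/MS spectra for LPE isomer pairs (sn-1 spectra carry the
m/z 196 headgroup-retention diagnostic; sn-2 spectra lack it and elute
earlier), write them as MGF, and call sn positions from the spectra.
"""

import argparse
import os

from brainlipid.chem import SnPosition, assign_sn_position, parse_lipid_name
from brainlipid.io import write_mgf, write_sn_calls
from brainlipid.simulate import generate_spectra


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", default="results/synthetic")
    ap.add_argument("--n-pairs", type=int, default=25)
    args = ap.parse_args()

    os.makedirs(args.data, exist_ok=True)
    species = ["LPE 22:6", "LPE 20:4", "LPE 22:5", "LPE 18:1", "LPE 18:0"]
    pairs = []
    for i in range(args.n_pairs):
        pairs.append((species[i % len(species)], "sn1"))
        pairs.append((species[i % len(species)], "sn2"))
    spectra, truth = generate_spectra(pairs, ppm_jitter=10.0, n_decoys=20,
                                      seed=args.seed)
    write_mgf(spectra, os.path.join(args.data, "lyso_spectra.mgf"))

    calls = {}
    correct = 0
    for spec in spectra:
        name = spec.title.split("|")[1]
        call = assign_sn_position(spec, parse_lipid_name(name), ppm_tol=10.0)
        calls[spec.title] = call
        correct += call.call.value == truth[spec.title]
    write_sn_calls(calls, os.path.join(args.data, "sn_calls.csv"))

    n = len(spectra)
    n_sn1 = sum(c.call is SnPosition.SN1 for c in calls.values())
    print(f"{n} spectra ({args.n_pairs} isomer pairs): {correct}/{n} calls match "
          f"the generating label; {n_sn1} called sn-1")
    print(f"wrote {args.data}/lyso_spectra.mgf and sn_calls.csv")


if __name__ == "__main__":
    main()
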