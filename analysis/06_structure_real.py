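#!/usr/bin/env python
"""Structural distances on the deposited RNAP structures (network needed).

Fetches the E. coli RNAP holoenzyme (PDB 4YG2) and initial transcribing
complex (PDB 4YLN) coordinate files from RCSB into results/structures/,
then computes:

* the Ca-Ca separation of the labelling sites (beta residue 106, beta'
  residue 284) on the holoenzyme — expected ~73 Å;
* the accessible-volume mean inter-dye distance R_AV for the Cy3B /
  Alexa647 pair on the closed-clamp structure — expected ~68.5 Å.

Once the files are present, tests/test_acceptance.py's structural-target
tests and scripts/acceptance.py report these numbers.
"""

import json
import sys
import urllib.request
from dataclasses import replace
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from clampfret import structure as sm  # noqa: E402

STRUCT = REPO / "results" / "structures"


def fetch(pdb_id: str) -> Path:
    STRUCT.mkdir(parents=True, exist_ok=True)
    path = STRUCT / f"{pdb_id.lower()}.pdb"
    if not path.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        print(f"fetching {url}")
        urllib.request.urlretrieve(url, path)
    return path


def find_chain(st, residue, fallbacks):
    for chain in fallbacks:
        try:
            st.find_atom(chain, residue)
            return chain
        except KeyError:
            continue
    raise KeyError(f"no chain with residue {residue} Ca among {fallbacks}")


def main() -> None:
    report = {}

    holo = sm.read_structure(fetch("4YG2"))
    beta = find_chain(holo, 106, ["C", "c", "B"])
    betap = find_chain(holo, 284, ["D", "d", "E"])
    d = sm.ca_distance(holo, (beta, 106), (betap, 284))
    report["ca_distance_labelling_sites_A"] = round(d, 1)
    print(f"4YG2 beta:106 Ca - beta':284 Ca = {d:.1f} A (expected ~73)")

    closed = sm.read_structure(fetch("4YLN"))
    beta = find_chain(closed, 106, ["C", "c", "B"])
    betap = find_chain(closed, 284, ["D", "d", "E"])
    acceptor = replace(sm.ALEXA647, chain=beta, residue=106)
    donor = replace(sm.CY3B, chain=betap, residue=284)
    r_av = sm.interdye_distance_av1(closed, donor, acceptor, grid_spacing=1.0)
    report["r_av_closed_clamp_A"] = round(r_av, 1)
    print(f"4YLN closed-clamp R_AV = {r_av:.1f} A (expected ~68.5)")

    out = REPO / "results" / "structure_real.json"
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
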