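"""Derive CYANA hydrogen-bond restraints from CSTC classes + reference geometry.

Builds an ideal 60-residue helix as the hydrogen-bond reference (donor i+4 ->
acceptor i), detects its backbone N-H...O=C bonds geometrically, marks
residues 5-56 as CSTC-positive, and emits two upper (.upl) and two lower
(.lol) distance bounds per matched donor — the conventional encoding of one
hydrogen bond for structure calculation.
"""

from pathlib import Path

from hbondnmr import hbond, structio
from hbondnmr.cstc import HBClass
from hbondnmr.synthdata import make_ideal_helix

model, truth = make_ideal_helix(60)
consensus = hbond.consensus_hbonds(structio.Ensemble(models=[model]))
classes = {
    r: (HBClass.HBONDED if 5 <= r <= 56 else HBClass.NOT_HBONDED)
    for r in range(1, 61)
}
restraints, unmatched = hbond.derive_restraints(classes, consensus)

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
n_up, n_lo = structio.write_cyana_restraints(
    restraints, out / "hbonds.upl", out / "hbonds.lol"
)
print(f"consensus hydrogen bonds in reference: {len(consensus)}")
print(f"CSTC-positive donors with a partner:   {n_up // 2}")
print(f"upper-bound restraints written (.upl): {n_up}  (2 per hydrogen bond)")
print(f"lower-bound restraints written (.lol): {n_lo}")
print(f"hydrogen bonded but unrestrained:      {len(unmatched)}")
print("first line:", (out / "hbonds.upl").read_text().splitlines()[0])
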