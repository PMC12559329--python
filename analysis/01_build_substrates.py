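#!/usr/bin/env python
"""Build the looped heteroduplex substrates used by all downstream analyses.

Writes the standard 3.2 kb circular plasmid carrying a 12-nt (CAG)4
extrahelical loop on the top strand, plus a (T)4-loop variant, as substrate
JSON + plasmid FASTA under results/substrates/, and prints the predicted
expansion/contraction product arithmetic as a sanity check.
"""

from pathlib import Path

from nickloop import contraction_product, expansion_product, substrates
from nickloop.pipeline import make_standard_substrate

OUT = Path(__file__).resolve().parent.parent / "results" / "substrates"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cag = make_standard_substrate()
    t4 = make_standard_substrate(loop_sequence="TTTT")
    for name, sub in (("cag4", cag), ("t4", t4)):
        sub.to_json(OUT / f"substrate_{name}.json")
        substrates.write_plasmid(sub.plasmid, OUT / f"plasmid_{name}.fasta")
        exp = expansion_product(sub)
        con = contraction_product(sub)
        print(f"[{name}] N={sub.N} loop={sub.loop.loop_sequence!r} (L={sub.L}) "
              f"on {sub.looped_strand} strand, boundaries "
              f"{sub.loop5_boundary}..{sub.loop3_boundary}")
        print(f"  expansion : both strands -> {len(exp.top)} nt "
              f"(opposite strand gains {substrates.revcomp(sub.loop.loop_sequence)!r})")
        print(f"  contraction: both strands -> {len(con.top)} nt (loop excised)")
    print(f"wrote substrate JSON + FASTA to {OUT}")


if __name__ == "__main__":
    main()
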