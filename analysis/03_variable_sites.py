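#!/usr/bin/env python
"""Variable alignment sites read against the secondary structure.

Aligns all cloned repeats of the birth-and-death condition (the alignment
is native: clones are gap-padded copies of one unit), finds the variable
columns, classifies each against the hairpin pairing map (unpaired /
wobble-neutral / CBC / mismatch) and flags candidate pseudogenes — repeat
copies carrying a broken designated-CBC pair.

Finding to look for: variable sites concentrate in unpaired (loop)
segments; stem changes are dominated by structurally neutral wobble
substitutions; mismatch carriers are rare and coincide with the planted
pseudogene truth.
"""

from pathlib import Path

import pandas as pd

from ribogap.seqio import Alignment, read_fasta
from ribogap.structure import find_variable_sites, flag_pseudogenes, read_dotbracket_file

ROOT = Path(__file__).resolve().parents[1]
TABLES = ROOT / "results" / "tables"


def main():
    TABLES.mkdir(parents=True, exist_ok=True)
    datadir = ROOT / "results" / "data" / "birth_death"
    clones = read_fasta(datadir / "clones.fasta")
    structure = read_dotbracket_file(datadir / "structure.dbn")
    # the emitted dot-bracket carries the pair map; loop annotations come
    # from the simulator's template (verified identical)
    from ribogap.simulate import default_structure

    template, _ = default_structure()
    assert template.pairs == structure.pairs
    structure = template
    designated = [
        tuple(int(x) - 1 for x in line.split())
        for line in (datadir / "designated_pairs.tsv").read_text().splitlines()
        if line and not line.startswith("#")
    ]
    ref = structure.reference
    from ribogap.seqio import SeqRecord, Source

    rows = [SeqRecord(id="REF", residues=ref, source=Source.DATABASE)] + clones
    aln = Alignment(records=rows, regions=list(structure.loops))
    sites = find_variable_sites(aln, structure, min_minor_count=3)
    site_rows = []
    for s in sites:
        site_rows.append(
            {
                "column": s.column + 1,
                "ref_position": None if s.ref_position is None else s.ref_position + 1,
                "loop": s.loop[0] if s.loop else "",
                "loop_local": s.loop[1] if s.loop else "",
                "states": "/".join(f"{b}:{c}" for b, c in sorted(s.state_counts.items())),
                "arity": s.arity,
                "dimorphic_snd": s.dimorphic,
                "substitution_class": s.substitution_class.value,
                "paired": s.paired,
                "effect": s.pairing_effect.value,
                "hemi_cbc": s.hemi_cbc,
            }
        )
    pd.DataFrame(site_rows).to_csv(TABLES / "variable_sites.tsv", sep="\t", index=False)

    report = flag_pseudogenes(aln, structure, sites, designated_pairs=set(designated))
    flag_rows = [
        {
            "seq_id": f.seq_id,
            "broken_pairs": ";".join(
                f"{ci + 1}:{cj + 1}={a}-{b}" for ci, cj, a, b in f.reasons
            ),
        }
        for f in report.flags
    ]
    pd.DataFrame(flag_rows, columns=["seq_id", "broken_pairs"]).to_csv(
        TABLES / "pseudogene_flags.tsv", sep="\t", index=False
    )

    n_unpaired = sum(1 for s in sites if not s.paired and s.ref_position is not None)
    n_anchored = sum(1 for s in sites if s.ref_position is not None)
    print(f"variable sites: {len(sites)} ({n_anchored} anchored to the reference)")
    print(
        f"unpaired fraction among variable sites: {n_unpaired / n_anchored:.2f} "
        f"(structure unpaired fraction {structure.unpaired_fraction():.2f})"
    )
    classes = pd.Series([s.substitution_class.value for s in sites]).value_counts()
    print("substitution classes:", dict(classes))
    print(f"pseudogene flags: {sorted(report.flagged_ids)}")
    print("region variability:", {k: round(v, 3) for k, v in report.region_variability.items()})


if __name__ == "__main__":
    main()
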