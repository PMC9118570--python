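#!/usr/bin/env python
"""Build the SIM/PRM transition list for the four glucagon species.

Generates every targeted ion from the glucagon sequence and the tracer
label stoichiometries: 4+ precursors for SIM (the unlabeled species
monitored from M+1, labeled species from M+0) and the 3+ b25/b26/b27
fragments for PRM, two isotopologues each.  Writes the list to
results/transitions.csv and prints the monitored m/z per species.
"""

from pathlib import Path

from glucagon_idms import builtin_species, transition_table
from glucagon_idms.species import write_transition_csv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    species = builtin_species()
    table = transition_table(species)
    OUT.mkdir(exist_ok=True)
    write_transition_csv(table, OUT / "transitions.csv")

    print(f"{len(table)} transitions for {len(species)} species")
    for name, grp in table.groupby("species", sort=False):
        ms1 = ", ".join(f"{v:.2f}" for v in grp[grp.ms_level == "MS1"].mz)
        print(f"  {name:6s} SIM 4+: {ms1}")
        for ion, g in grp[grp.ms_level == "MS2"].groupby("ion"):
            mzs = ", ".join(f"{v:.2f}" for v in g.mz)
            print(f"         PRM {ion} 3+: {mzs}")
    print(f"wrote {OUT / 'transitions.csv'}")


if __name__ == "__main__":
    main()
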