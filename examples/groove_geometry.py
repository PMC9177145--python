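"""Groove descriptors on a toy peptide-MHC structure panel.

Builds coordinate fixtures whose four descriptors hit known targets
(the C1-like and C2-like values), measures them back with the geometry
module, and compares the groups with Welch t-tests — the same workflow
one would run over real deposited structures via a manifest CSV.
"""

import tempfile
from pathlib import Path

from hlacpep import group_geometry_stats, load_structure, measure_structure
from hlacpep.synth import build_toy_panel

with tempfile.TemporaryDirectory() as tmp:
    paths = build_toy_panel(Path(tmp), noise_sd=0.08, seed=1)
    records = []
    for path in paths:
        group = "C1" if path.stem.startswith("C1") else "C2"
        records.append(measure_structure(load_structure(path, group=group)))

    print("per-structure descriptors:")
    for rec in records:
        print(
            f"  {rec.structure_id}: d77-pΩ1 {rec.d77_pomega1:.2f} A, "
            f"Tyr171-Nterm {rec.d_tyr171_nterm:.2f} A, "
            f"pΩ1/Val76 {rec.d_val76_side:.2f} A, ω {rec.omega_term:.1f}°"
        )

    stats = group_geometry_stats(records).set_index("descriptor")
    row = stats.loc["d77_pomega1"]
    print(
        f"\nd77-pΩ1: C1 {row['mean_c1']:.2f} ± {row['sd_c1']:.2f} A vs "
        f"C2 {row['mean_c2']:.2f} ± {row['sd_c2']:.2f} A (Welch p = {row['p_welch']:.2g})"
    )
    print(
        "The ~1 A gap shows the peptide's penultimate residue sitting deeper\n"
        "in the C1 groove (Ser77) than in the C2 groove (Asn77)."
    )
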