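"""Load a raw edge list, clean it, translate IDs, keep the giant component.

Raw interaction exports typically contain self-interactions, both
orientations of the same pair, and IDs from a different namespace than
the annotation tables.  This script writes a small messy TSV, loads it
(simplification is automatic and reported), applies an ID translation
table, and extracts the giant component.
"""

import tempfile
from pathlib import Path

from vesselflow import IdMapping, apply_id_mapping, giant_component, load_edge_list

workdir = Path(tempfile.mkdtemp())
raw = workdir / "raw_interactions.tsv"
raw.write_text(
    "# protein_a\tprotein_b\n"
    "ENSP01\tENSP02\n"
    "ENSP02\tENSP01\n"   # duplicate in the reverse orientation
    "ENSP01\tENSP01\n"   # self-interaction
    "ENSP02\tENSP03\n"
    "ENSP04\tENSP05\n"   # separate component
)

net, report = load_edge_list(raw)
print("cleanup report:", report)

mapping = IdMapping([
    ("ENSP01", "P00533"), ("ENSP02", "P62993"),
    ("ENSP03", "Q07889"), ("ENSP04", "P12931"),
    # ENSP05 has no translation: dropped with its edges, and reported
])
mapped, map_report = apply_id_mapping(net, mapping)
print("untranslated IDs :", map_report["untranslated"])
print("nodes after map  :", sorted(mapped.nodes))

giant = giant_component(mapped)
print(f"giant component  : {giant.n_nodes} of {mapped.n_nodes} nodes "
      f"({sorted(giant.nodes)})")
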