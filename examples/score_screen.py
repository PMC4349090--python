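"""Score a stress screen and cluster the sensitivity profiles.

Builds noise-free spot-assay readouts for three toy strains, scores them
into the ordinal 2/1/0/-1 matrix, then computes the collection-scale counts
on the synthetic 281-strain call table and exports a clustered CDT/GTR pair.
"""

import tempfile
from pathlib import Path

from delkit.screen import (
    cluster_profiles,
    count_multistress,
    export_clustered,
    score_readouts,
    select_condition_set,
)
from delkit.synthetic import generate_growth_readouts, synthetic_phenotype_table

effects = {
    "delA": {"hydroxyurea": "sensitive", "bleomycin": "very_sensitive"},
    "delB": {"latrunculin_A": "sensitive", "SDS": "resistant"},
    "delC": {},
}
matrix = score_readouts(generate_growth_readouts(effects))
print("toy matrix (nonzero cells):")
for strain in matrix.strains:
    row = matrix.data.loc[strain]
    hits = {c: int(v) for c, v in row.items() if v != 0}
    print(f"  {strain}: {hits or 'no phenotype'}")

table = synthetic_phenotype_table(seed=0)
_, n1, _ = count_multistress(table, 1)
_, n3, pct = count_multistress(table, 3)
dna = select_condition_set(table, ["hydroxyurea", "bleomycin", "MMS"])
print(f"\nsynthetic 281-strain collection: {n1} strains affected by >=1 stress, "
      f"{n3} by >=3 ({pct:.1f}% of the collection), "
      f"{len(dna)} sensitive to a DNA-metabolism drug")

result = cluster_profiles(table, metric="euclidean")
with tempfile.TemporaryDirectory() as td:
    paths = export_clustered(table, result, Path(td) / "screen")
    print(f"clustered-table export: {[p.name for p in paths.values()]} "
          f"({len(result.strains) - 1} join nodes)")

# Codes: 2 = very sensitive, 1 = sensitive, 0 = not sensitive, -1 = resistant.
# The CDT/GTR pair can be opened directly in Java TreeView.
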