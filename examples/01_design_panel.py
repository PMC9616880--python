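"""Design a control-adaptor panel and gene-specific control sequences.

The default panel is 72 adaptors of 90 nt: a shared 30-nt 5' burn-in
segment, a 30-nt variable segment unique to each adaptor (windows of a
6-mer-complete de Bruijn source, screened for hairpins and, optionally,
homology to a reference database), and a shared 30-nt 3' segment.
"""

import numpy as np

from captorkit import DesignConfig, design_panel
from captorkit.design import design_gene_controls, max_hairpin_stem
from captorkit.io import BedInterval

panel = design_panel(DesignConfig(rng_seed=0))
kmers = {a.variable[i:i + 6] for a in panel for i in range(25)}
print(f"panel: {len(panel)} adaptors x {len(panel[0].full_sequence)} nt")
print(f"shared constant5: {panel[0].constant5}")
print(f"first variable region: {panel[0].variable}")
print(f"distinct 6-mers covered by variable regions: {len(kmers)} of 4096")
print(f"max hairpin stem across panel: "
      f"{max(max_hairpin_stem(a.full_sequence) for a in panel)} nt (<= 8)")

# gene-specific controls: exon-sized slices of a reference contig
rng = np.random.default_rng(1)
contig = "".join("ACGT"[b] for b in rng.integers(0, 4, 6000))
controls = design_gene_controls(
    {"geneA": contig},
    [BedInterval("geneA", 100, 5272, "exon_fwd"),
     BedInterval("geneA", 200, 2254, "exon_rev", "0", "-")])
for g in controls:
    contig_name, start, end, strand = g.source_region
    print(f"gene control {g.id}: {len(g.sequence)} nt from "
          f"{contig_name}:{start}-{end}({strand})")

# The panel tiles ~1500 distinct 6-mers (72 x 30 nt cannot hold all 4096);
# every adaptor passes the hairpin screen; gene controls are exact
# strand-aware slices that will serve as matched error-profile references.
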