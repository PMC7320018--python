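"""AP-MS / BioID interactor filtering on a synthetic replica screen.

Applies the two-stage filter — SAINTexpress BFDR <= 0.01, then the
Crapome contaminant band (seen <= 20 times in 411 negative controls) —
and classifies the surviving genes against a known-interactor list.
The screen is synthetic but mirrors the composition of a published
TBC1D9 screen, so the counts land on the published values.
"""

from tnbcscm.interactors import (
    distinct_prey_genes,
    filter_bfdr,
    filter_crapome,
    overlap_report,
    synthetic_saint_screen,
)

screen = synthetic_saint_screen("TBC1D9", seed=0)
for assay, records in (("AP-MS", screen.apms), ("BioID", screen.bioid)):
    significant = filter_bfdr(records, cutoff=0.01)
    clean = filter_crapome(significant, screen.crapome, max_count=20)
    print(f"{assay}: {len(distinct_prey_genes(records))} identified -> "
          f"{len(distinct_prey_genes(significant))} significant (BFDR<=0.01) -> "
          f"{len(distinct_prey_genes(clean))} after contaminant removal")

report = overlap_report(
    distinct_prey_genes(screen.apms),
    distinct_prey_genes(screen.bioid),
    screen.known_genes,
)
print(f"known interactors found: {sorted(report.known_apms_only)} by AP-MS only, "
      f"{sorted(report.known_bioid_only)} by BioID only, "
      f"{sorted(report.known_both)} by both")
# Counts are distinct prey genes (a prey may occupy several table rows).
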