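"""Screen DEGs in each contrast and intersect the three regulated sets.

Applies the FDR <= 0.05 and |log2FC| >= 1 gates, partitions the regulated
sets into the seven Venn regions, and estimates the log2FC dispersion of
the SWL-unique responders — the quantity that motivates the classifier
tolerance sigma = 0.50.  Writes the regulated sets and the Venn report
under results/selection/.
"""

import json
from pathlib import Path

from stressmodes.feature_selection import (
    estimate_sigma,
    select_deg,
    venn_partition,
)
from stressmodes.tables_io import read_contrast_table

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "selection"


def main() -> None:
    tables = {
        label: read_contrast_table(DATA / f"{label}.tsv", label, "transcript")
        for label in ("ST", "WL", "SWL")
    }
    regulated = {label: select_deg(t) for label, t in tables.items()}
    venn = venn_partition(regulated["ST"], regulated["WL"], regulated["SWL"])

    OUT.mkdir(parents=True, exist_ok=True)
    for label, reg in regulated.items():
        with open(OUT / f"regulated_{label}.tsv", "w") as fh:
            fh.write("feature_id\tstatus\n")
            for fid in sorted(reg.members):
                fh.write(f"{fid}\t{reg.members[fid]}\n")
        print(f"{label}: {len(reg)} regulated "
              f"({sum(1 for s in reg.members.values() if s == 'up')} up)")

    swl_unique_lfc = [tables["SWL"].log2fc(f) for f in venn.unique("SWL")]
    sigma_hat = estimate_sigma(swl_unique_lfc)

    report = {"venn_counts": venn.counts(), "sigma_swl_unique": sigma_hat}
    (OUT / "venn_report.json").write_text(json.dumps(report, indent=2))
    with open(OUT / "venn_regions.tsv", "w") as fh:
        fh.write("region\tcount\tids\n")
        for sig in sorted(venn.regions, key=lambda s: (len(s), sorted(s))):
            ids = sorted(venn.regions[sig])
            fh.write(f"{'+'.join(sorted(sig))}\t{len(ids)}\t{','.join(ids)}\n")

    print(f"Venn regions: {venn.counts()}")
    print(f"common features eligible for mode classification: {len(venn.common)}")
    print(f"sample sd of SWL-unique log2FC: {sigma_hat:.3f} "
          f"(classifier default sigma stays 0.50)")


if __name__ == "__main__":
    main()
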