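#!/usr/bin/env python
"""Call the host response: early/late vs the uninfected control, and late vs
early, with the compound threshold rules.

Host genes are Total-Count normalized against each other (host_only scope).
Control comparisons combine the |log2FC| > 1.5 gate with the 2-SD control
gate; late-vs-early uses a pooled Student t-test at p < 0.01.  Tallies are
printed the way the report layer formats them (genome fractions to 2 dp,
up-among-DE to 1 dp) and recovery against the planted effects is scored.

Reads results/dataset/, writes results/de_*.tsv.
"""

from pathlib import Path

import pandas as pd

from phagetime.de import (
    de_call_late_vs_early,
    de_call_vs_control,
    format_tally,
    tally_de,
)
from phagetime.io import read_counts, read_gff3, write_table
from phagetime.normalize import total_count_normalize

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "dataset"
    features = {f.gene_id: f for f in read_gff3(data / "annotation.gff3")}
    counts = read_counts(data / "counts.tsv", data / "samples.tsv", features)
    norm = total_count_normalize(counts, "host_only")
    early = [s.sample_id for s in counts.samples if s.time_min in (2, 5)]
    late = [s.sample_id for s in counts.samples if s.time_min in (28, 35, 42, 49)]
    n_host = sum(1 for g in counts.gene_ids if features[g].organism == "host")

    truth = pd.read_csv(data / "truth_host_effects.tsv", sep="\t")
    tables = {
        "early_vs_control": de_call_vs_control(
            norm, early, "t00", comparison="early_vs_control"),
        "late_vs_control": de_call_vs_control(
            norm, late, "t00", comparison="late_vs_control"),
        "late_vs_early": de_call_late_vs_early(norm, early, late),
    }
    for name, table in tables.items():
        write_table(ROOT / f"de_{name}.tsv", table, f"host DE; {name}")
        t = format_tally(tally_de(table, n_host))
        print(f"{name}: {t['n_up']} up, {t['n_down']} down "
              f"-> {t['genome_pct_de']}% of {n_host} host genes DE, "
              f"{t['up_of_de_pct']}% of DE genes up")
        planted = truth[truth.comparison == name]
        if len(planted):
            status = dict(zip(table.gene_id, table.status))
            hit = sum(
                (status.get(r.gene_id) == ("up" if r.effect_log2fc > 0 else "down"))
                for r in planted.itertuples()
            )
            print(f"  planted-effect recovery: {hit}/{len(planted)}")


if __name__ == "__main__":
    main()
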