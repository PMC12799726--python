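"""Panel QC, the distinct-SNP screen and single-marker association.

Uses the built-in demo dataset: a 120-line panel in which three markers
are fixed for opposite homozygous alleles between the 7 most and 10 least
drought-tolerant lines (by true aggregate value) and act as a tolerance
haplotype on GYPS and PW.
"""

import json
import tempfile
import warnings
from pathlib import Path

import pandas as pd
import wheatqg as w

with tempfile.TemporaryDirectory() as tmp:
    paths = w.make_demo_dataset(Path(tmp), n_genotypes=120, n_markers=500, seed=1)
    truth = json.loads(Path(paths["truth"]).read_text())
    snp = w.read_genotypes_csv(paths["genotypes_csv"])

    filtered, summary = w.filter_markers(snp)
    print(f"QC: {summary.n_markers_in} -> {summary.n_markers_out} markers, "
          f"{summary.n_samples_in} -> {summary.n_samples_out} samples")

    screen = w.distinct_snp_screen(filtered, truth["group_a"], truth["group_b"])
    print(f"distinct markers (tolerant vs susceptible): {screen.marker_ids} "
          f"({screen.fraction:.2%} of the panel)")

    thr = w.significance_thresholds(filtered.n_markers)
    print(f"significance thresholds: fixed p <= {thr.fixed}, "
          f"suggestive p <= {thr.suggestive:.2e} (1/N)")

    obs = w.read_phenotypes(paths["phenotypes"])
    means = w.genotype_means(obs, "D2020")
    for marker in screen.marker_ids:
        res = w.single_marker_assoc(filtered, marker, means["GYPS"].rename("GYPS"))
        print(f"  {marker}: GYPS effect = {res.effect:.3f} g, p = {res.p_value:.2e}")

    r2 = w.ld_r2(filtered, screen.marker_ids[0], screen.marker_ids[1])
    print(f"LD r^2 between the first two screened markers: {r2:.3f}")
    # The screened markers recover the planted tolerance haplotype; their
    # positive GYPS effects are the per-allele-class yield advantage, and
    # high LD between them means they tag the same haplotype.
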