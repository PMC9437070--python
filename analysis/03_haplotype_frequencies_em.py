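"""EM haplotype-frequency estimates vs the generator's known truth.

Runs on the "hf-table" cohort, whose per-group (*1a,*1b,*5,*15) frequencies
are the published haplotype rows; the EM estimates from the unphased
genotypes should recover them within ~3 SE (observed-information SEs).
"""

import json

from _common import COHORTS, TABLES, load_cohort
from slco1b1.haplotypes import (
    HAPLOTYPE_NAMES,
    em_haplotype_frequencies,
    haplotype_frequency_se,
    two_locus_counts,
)


def main() -> None:
    table = load_cohort("hf-table")
    truth = json.loads((COHORTS / "hf-table" / "truth.json").read_text())
    truth_f = {g["label"]: g["hap_freqs"] for g in truth["groups"]}
    TABLES.mkdir(parents=True, exist_ok=True)
    out = TABLES / "haplotype_em.tsv"
    with open(out, "w") as fh:
        fh.write("group\thaplotype\ttruth_pct\tem_pct\tse_pct\tz\tn_iter\n")
        for group in ["Total"] + table.groups:
            tlc = two_locus_counts(table, group)
            hf = em_haplotype_frequencies(tlc)
            try:
                se = haplotype_frequency_se(tlc, hf)
            except ValueError:
                # estimate on the simplex boundary (a haplotype unobserved in
                # a small group): no finite observed-information SE
                se = None
                print(f"{group}: boundary estimate, SEs unavailable")
            print(f"{group}: EM converged in {hf.n_iter} iterations, loglik {hf.loglik:.2f}")
            for i, name in enumerate(HAPLOTYPE_NAMES):
                est = float(hf.as_array()[i])
                se_str = f"{100 * se[i]:.2f}" if se is not None else "NA"
                if group == "Total":
                    t_str, z_str = "", ""
                else:
                    t = truth_f[group][name]
                    z_str = f"{(est - t) / se[i]:+.2f}" if se is not None else "NA"
                    t_str = f"{100 * t:.2f}"
                    print(f"  {name:4s} truth {100 * t:6.2f}%  EM {100 * est:6.2f}%  z={z_str}")
                fh.write(
                    f"{group}\t{name}\t{t_str}\t{100 * est:.2f}\t{se_str}\t{z_str}\t{hf.n_iter}\n"
                )
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
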