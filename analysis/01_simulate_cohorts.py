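"""Generate the two synthetic study cohorts (1050 samples: 587/387/76).

The published frequency tables are internally inconsistent between their
haplotype rows and their MAF/phenotype rows, so two cohorts are simulated:
"hf-table" reproduces the published haplotype-frequency rows, and
"maf-consistent" reproduces the published MAFs and phenotype counts.  Each
cohort is written as VCF + sample metadata + generative truth.
"""

import json

from _common import SEED, ensure_cohort


def main() -> None:
    for preset in ("hf-table", "maf-consistent"):
        out = ensure_cohort(preset)
        truth = json.loads((out / "truth.json").read_text())
        print(f"[{preset}] seed={SEED} -> {out}")
        for g in truth["groups"]:
            freqs = ", ".join(f"{k}={v:.4f}" for k, v in g["hap_freqs"].items())
            print(f"  {g['label']}: n={g['n_samples']}  {freqs}")


if __name__ == "__main__":
    main()
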