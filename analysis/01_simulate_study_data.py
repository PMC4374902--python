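#!/usr/bin/env python
"""Generate the synthetic study bundles every later analysis step consumes.

Writes a confirmation-style study (MHC-SF items, covariates, 52 CTRA genes +
8 marker transcripts, a true eudaimonic effect of -0.5 SD), a smaller
discovery-style sample for the pooled analysis, and a generalization-style
study (Ryff-PWB, 53 genes).  Files go under scratch/study_data/ (regenerated
on demand; every file round-trips through the package readers).
"""
from pathlib import Path

from ctra_wellbeing.synthetic import StudyBundleConfig, gen_study_bundle

OUT = Path(__file__).resolve().parents[1] / "scratch" / "study_data"

BUNDLES = {
    # study conditions: confirmation n=122 (52 genes, IL6 dropped), discovery
    # n=76 (53 genes), generalization n=107 (53 genes, Ryff-PWB)
    "confirmation": StudyBundleConfig(
        study="confirmation", n_subjects=122,
        b_true={"eudaimonic": -0.5}, seed=20_001,
    ),
    "discovery": StudyBundleConfig(
        study="confirmation", n_subjects=76,
        b_true={"eudaimonic": -0.5}, exclude_genes=(), seed=20_002,
    ),
    "generalization": StudyBundleConfig(
        study="generalization", n_subjects=107,
        b_true={"total_pwb": -0.4}, exclude_genes=(), seed=20_003,
    ),
}


def main() -> None:
    for name, config in BUNDLES.items():
        paths = gen_study_bundle(config, OUT / name)
        print(f"[{name}] n={config.n_subjects}, effect={dict(config.b_true)}")
        for kind, p in paths.items():
            print(f"  {kind:10s} {p}")


if __name__ == "__main__":
    main()
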