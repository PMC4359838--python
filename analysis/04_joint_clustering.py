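#!/usr/bin/env python
"""Joint clustering of latent variables per syndrome factor.

For each of the five shipped syndrome factors (Qi-stagnation, dampness,
blood-stasis, heat, deficiency of healthy-Qi) this pools the significant
manifestations of the factor's member latents, fits a fresh latent class
variable Z over the pooled columns (cardinality by BIC), reads Z's typical
manifestations off its information curve, applies the declarative expert
exclusions, and splits factors whose Z has three or more states into
sub-syndromes. Reports go under results/factors/.
"""

import argparse
from pathlib import Path

from ltmclust.data import read_symptom_matrix
from ltmclust.jcm import build_jcm, study_factor_map
from ltmclust.model import LatentTreeModel

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--base-model", type=Path,
                    default=ROOT / "results" / "curves" / "model_base.json")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "factors")
    args = ap.parse_args()

    data = read_symptom_matrix(args.cohort / "cohort.csv")
    base = LatentTreeModel.load(args.base_model)
    fmap = study_factor_map()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    fmap.save(out / "factor_map.json")

    for i, factor in enumerate(fmap.factors, start=1):
        jcm = build_jcm(base, data, factor, fmap, z_name=f"Z{i}",
                        seed=args.seed, curve_seed=args.seed)
        (out / f"{factor}.tsv").write_text(
            "\n".join(jcm.report_lines()) + "\n", "utf-8"
        )
        jcm.curve.to_tsv(out / f"{factor}_curve.tsv")
        jcm.curve.plot(out / f"{factor}_curve.png")
        print(f"{factor} ({jcm.z_name}, {jcm.cardinality} states): "
              f"typical manifestations = {', '.join(jcm.selected)}")
        for s in jcm.subsyndromes:
            if s.curve is not None:
                s.curve.to_tsv(out / f"{factor}_{s.name}_curve.tsv")
            print(f"  sub-syndrome {s.name}: {', '.join(s.selected)}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
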