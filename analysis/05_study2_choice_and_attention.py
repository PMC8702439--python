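"""Fixed-battery choice proportions and attribute attention, with the
qualitative pattern summary across all analyses.

The proportion of smaller-sooner choices is the dependent variable of the
2x2 mixed ANOVA; the attention probe is tested with uncorrected Pearson
chi-squares (effect size r = sqrt(chi2/N)).
"""

import json
import sys
from pathlib import Path

import pandas as pd

from delaydisc import io as dio
from delaydisc import stats as gs

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = dio.read_dataset(RESULTS / "data" / "study2", ["choices", "attention"])
    props = gs.proportion_ss(data["choices"]).rename(columns={"proportion_ss": "value"})
    res = gs.mixed_anova_2x2(props, value="value")
    print("proportion of SS choices, 2x2 mixed ANOVA:")
    print(res.tidy().to_string(index=False))
    means = props.groupby(["group", "condition"])["value"].mean()
    print("cell means:\n" + means.to_string())
    res.tidy().to_csv(RESULTS / "anova_proportion_ss.csv", index=False)

    chi = {}
    for column in ("first_attention", "majority_attention"):
        table = gs.attention_table(data["attention"], column)
        out = gs.chi_square_2x2(table)
        chi[column] = {"chi2": out.chi2, "df": out.df, "p": out.p, "r": out.effect_r}
        print(f"\n{column}: chi2({out.df}) = {out.chi2:.2f}, p = {out.p:.4f}, "
              f"r = {out.effect_r:.2f}")
    (RESULTS / "attention_chi2.json").write_text(json.dumps(chi, indent=2))

    # qualitative pattern across the whole analysis chain
    checks = {}
    obj = pd.read_csv(RESULTS / "anova_objective_k.csv").set_index("effect")
    subj = pd.read_csv(RESULTS / "anova_subjective_k.csv").set_index("effect")
    alpha = pd.read_csv(RESULTS / "anova_perception_alpha.csv").set_index("effect")
    checks["objective_interaction_present"] = bool(obj.loc["group:condition", "p"] < 0.05)
    checks["alpha_group_effect"] = bool(alpha.loc["group", "p"] < 0.05)
    checks["subjective_no_condition_effect"] = bool(subj.loc["condition", "p"] >= 0.05)
    checks["attention_first_significant"] = bool(chi["first_attention"]["p"] < 0.05)
    print("\npattern checks:")
    for name, ok in checks.items():
        print(f"  {name}: {'PASS' if ok else 'FAIL'}")
    (RESULTS / "pattern_checks.json").write_text(json.dumps(checks, indent=2))


if __name__ == "__main__":
    sys.exit(main())
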