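#!/usr/bin/env python
"""Extract transdiagnostic dimensions from the questionnaire items.

Builds the heterogeneous (polychoric) correlation matrix over the 176
ordinal items of attention-check passers, selects the factor count with the
CNG scree test, fits the ML factor model with oblimin rotation, computes
Thurstone regression factor scores, and (optionally) bootstrap CIs for the
loadings.

Reads results/cohort/; writes results/factors/.
"""

import argparse
from pathlib import Path

import pandas as pd

from tempdisc import (
    bootstrap_loading_cis,
    cng_factor_count,
    factor_scores,
    fit_ml_efa,
    hetcor_matrix,
)
from tempdisc.cohort import FACTORS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=5)
    ap.add_argument("--cohort-dir", type=str, default="results/cohort")
    ap.add_argument("--out", type=str, default="results/factors")
    ap.add_argument("--n-boot", type=int, default=0,
                    help="bootstrap replicates for loading CIs (0 = skip; "
                    "the emulated study design uses 1000)")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(Path(args.cohort_dir) / "cohort.csv")
    cohort = cohort[~cohort["attention_check_fail"]].reset_index(drop=True)
    import yaml

    codebook = pd.DataFrame(
        yaml.safe_load((Path(args.cohort_dir) / "cohort.codebook.yaml").read_text())["items"]
    )
    items = list(codebook["item"])
    table = cohort[items]
    var_types = {c: "ordinal" for c in items}

    het = hetcor_matrix(table, var_types)
    het.to_frame().to_csv(out / "hetcor.csv")
    pd.DataFrame({"eigenvalue": het.eigenvalues}).to_csv(out / "eigenvalues.csv", index=False)
    print(f"heterogeneous correlation matrix: {len(items)} items, "
          f"smoothing applied: {het.smoothing_applied}")
    print("leading eigenvalues:", het.eigenvalues[:6].round(2).tolist())

    nf = cng_factor_count(het.eigenvalues)
    print(f"CNG scree test selects {nf} factors")
    sol = fit_ml_efa(het, nf)
    if nf == len(FACTORS):
        # name each factor after the dominant construct among its salient items
        # (the automated analogue of labelling factors by inspecting loadings)
        construct = codebook.set_index("item")["factor"]
        labels, used = [], set()
        for col in sol.loadings.columns:
            salient = sol.loadings.index[sol.loadings[col].abs() > 0.3]
            votes = construct.loc[salient].value_counts()
            name = next((f for f in votes.index if f not in used), col)
            labels.append(name)
            used.add(name)
        sol.loadings.columns = labels
        sol.labels = labels
    else:
        labels = list(sol.loadings.columns)
    sol.loadings.round(4).to_csv(out / "loadings.csv")
    pd.DataFrame(sol.factor_corr, index=labels, columns=labels).round(4).to_csv(
        out / "factor_correlations.csv"
    )
    print("factor correlations:\n", pd.DataFrame(sol.factor_corr, index=labels,
                                                 columns=labels).round(2))
    for lab in labels:
        top = sol.loadings[lab].abs().nlargest(3)
        print(f"  {lab}: top loadings {list(top.index)}")

    scores = factor_scores(sol, table)
    scores.insert(0, "participant_id", cohort["participant_id"].to_numpy())
    scores.to_csv(out / "factor_scores.csv", index=False)

    if args.n_boot:
        cis = bootstrap_loading_cis(table, var_types, nf, n_boot=args.n_boot,
                                    seed=args.seed, reference=sol)
        cis.round(4).to_csv(out / "loading_cis.csv")
        print(f"bootstrap loading CIs written ({args.n_boot} replicates)")
    print(f"wrote {out}/loadings.csv, factor_scores.csv, eigenvalues.csv")


if __name__ == "__main__":
    main()
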