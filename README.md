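# fpromethee

Fuzzy PROMETHEE I/II outranking analysis for multi-criteria decisions —
built around the problem of choosing among genome-sequencing platforms, but
applicable to any decision table that mixes hard numbers (instrument cost,
error rate, run output) with verbal expert judgments ("throughput: Very
High").

## Who it is for

Labs, health-technology assessors, and operational researchers who need a
defensible ranking of alternatives evaluated on many conflicting criteria,
where some evaluations and all importance weights come from experts as
linguistic terms rather than measurements.

## The method

1. **Fuzzy layer.** Linguistic terms on a five-level scale
   (VL, L, M, H, VH) map to triangular fuzzy numbers; the default scale is
   VH=(0.75, 1, 1), H=(0.50, 0.75, 1), M=(0.25, 0.50, 0.75),
   L=(0, 0.25, 0.50), VL=(0, 0, 0.25). Each fuzzy number (N, a, b) — peak N,
   left spread a, right spread b — is defuzzified with the **Yager index**
   (3N − a + b)/3, which equals the triangle centroid (l + m + u)/3.
2. **Outranking.** For each ordered pair of alternatives and each criterion
   k, the signed advantage d is pushed through a preference function
   P_k(d) ∈ [0, 1]; the default is the **Gaussian** type
   P(d) = 1 − exp(−d²/2s²) with spread s set to the criterion column's
   sample standard deviation, so preferences are graded and scale-free.
   The aggregated preference index is π(a, b) = Σ_k w_k P_k(d_k(a, b)) with
   weights normalized to sum 1.
3. **Flows and ranking.** Positive flow Φ⁺(a) = (1/(n−1)) Σ_b π(a, b)
   (strength), negative flow Φ⁻(a) = (1/(n−1)) Σ_b π(b, a) (weakness).
   PROMETHEE I builds a partial preorder (preferred / indifferent /
   incomparable) from the two flows; PROMETHEE II ranks by the net flow
   Φ_net = Φ⁺ − Φ⁻, which always sums to zero over the alternatives.
   Unicriterion net flows φ_k(a) decompose Φ_net into per-criterion
   strengths (φ_k > 0) and weaknesses (φ_k < 0).
4. **Sensitivity.** Rankings are re-run under targeted weight changes
   (e.g. demoting six Very-High criteria to High) or Monte Carlo weight
   noise, and compared via rank displacement and Kendall's τ-b.

## Worked example

The packaged study-structure fixture has 15 sequencing platforms × 20
criteria with the published weight design (10 Very-High, 7 High, 3 Moderate;
costs, error rate, processing time and loading volume minimized). Its cell
values are synthetic draws — the study's vendor-spec measurements were never
published — so the ranking below illustrates the machinery, not the study's
result.

```python
import fpromethee as fp

matrix = fp.paper_fixture()          # 15 x 20, synthetic cells
table = fp.rank_matrix(matrix)       # PROMETHEE II
print(table.to_frame().round(4).to_string(index=False))
```

```
 rank alternative  phi_net  phi_plus  phi_minus
    1         SMR   0.1940    0.3170     0.1231
    2         ION   0.1275    0.2913     0.1638
    3         ILM   0.1070    0.2685     0.1615
    ...
   15         ONT  -0.1641    0.1213     0.2854
```

Each row gives the alternative's strength (Φ⁺), weakness (Φ⁻) and overall
standing (Φ_net = Φ⁺ − Φ⁻); the column of net flows sums to 0. Replaying the
six-criterion weight demotion experiment:

```python
report = fp.run_weight_change_experiment(matrix, fp.study_weight_changes(matrix))
print(report.concordance)            # 0.9238  (Kendall tau-b vs baseline)
print(len(report.reversals))         # 4 pairwise rank reversals
```

The same pipeline is scriptable from the shell:

```bash
fpromethee simulate --out demo --seed 11 --plant-winner A2
fpromethee rank --matrix demo/matrix.csv --config demo/criteria.yaml --out demo/report
fpromethee sensitivity --matrix demo/matrix.csv --config demo/criteria.yaml \
    --out demo/sens --set-weight C8=H --mc-noise 0.2 --seed 11
```

Input formats: a CSV decision matrix (rows = alternatives, columns =
criterion ids, cells numeric or VH/H/M/L/VL) plus a YAML/JSON criteria
config (direction, weight, preference function, optional custom fuzzy
scale). See `docs/methods.md` for the full model description and design
choices.

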