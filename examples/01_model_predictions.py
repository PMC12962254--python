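"""Evaluate the five justifiability models over the 3 x 3 prevalence design.

Each model maps a (target, referent) prevalence pair to a raw score, then the
scores are min-max normalized onto the -3..+3 rating scale.  The printed
grids are the predicted response patterns the experiment discriminates:
'absolute' varies only down the rows, 'subtraction' only across the columns,
the fraction models concentrate their action in the low-prevalence row, and
the hybrid in the high-prevalence row.
"""

from genjust import MODELS, prediction_table

for model in MODELS:
    table = prediction_table(model, value_f=1.5)
    grid = table[table["dangerous"] == 0].pivot(
        index="abs_level", columns="rel_level", values="normalized")
    grid = grid.loc[["low", "intermediate", "high"],
                    ["negative", "equal", "positive"]]
    print(f"\n{model} (non-dangerous cells, normalized to -3..+3)")
    print(grid.round(2).to_string())
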