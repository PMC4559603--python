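"""Execute an app in a live R session and capture its typed output.

Generates a ten-column expression-like table, runs the shipped correlation
app (multi-column numeric input, Pearson/Spearman choice, table output)
against a real R interpreter, and prints the collected 10x10 correlation
matrix. The app's script assigns its result to the output parameter's
variable; the engine fetches it and files it under the user-chosen
destination name ("corr" here).
"""

import tempfile

from tabbench import RBackend, discover_apps, run_app
from tabbench.fixtures import TableConfig, gen_app_bundle, gen_table

table = gen_table(TableConfig(n_rows=200, n_columns=10, seed=0))
cols = table.numeric_columns()

with tempfile.TemporaryDirectory() as tmp:
    gen_app_bundle("correlation", tmp)
    (spec,) = discover_apps(tmp)
    with RBackend() as backend:
        result = run_app(
            spec,
            table,
            {"input_columns": cols, "input_method": "pearson",
             "output_corr": "corr"},
            backend,
        )

print("status:", result.status)
corr = result.outputs["corr"]
print(f"output table 'corr': {corr.shape[0]} x {corr.shape[1]}")
print(corr.iloc[:4, :4].round(3).to_string())
# Diagonal entries are 1 (each sample with itself); off-diagonal values are
# Pearson correlations between independent log-normal columns, so near 0.
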