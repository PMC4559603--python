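"""Auto-generate an interface from a typed parameter manifest.

Builds the SimplePlot app bundle (a 2-D scatter script plus its JSON
manifest), discovers it from disk, and prints the widget model and CLI
flags that the manifest alone determines: each parameter type maps to a
fixed widget kind, labels fall back to a rule over the variable name, and
column-typed parameters list the columns of whatever table is attached.
"""

import tempfile
from pathlib import Path

from tabbench import discover_apps, interface_model, render_cli
from tabbench.fixtures import TableConfig, gen_app_bundle, gen_table

with tempfile.TemporaryDirectory() as tmp:
    gen_app_bundle("simpleplot", tmp)
    (spec,) = discover_apps(tmp)

    print(f"app: {spec.app_name} ({len(spec.params)} parameters, "
          f"{len(spec.required_params)} required)")

    table = gen_table(TableConfig(n_rows=10, n_columns=3, seed=0))
    print("\nwidget model against a 3-numeric-column table:")
    for w in interface_model(spec, table):
        choices = f" choices={w.choices}" if w.choices else ""
        print(f"  {w.variable_name:13s} {w.widget_kind:17s} "
              f"label={w.resolved_label!r}{choices}")

    print("\nCLI flags derived from the same manifest:")
    print(" ", " ".join(arg.flag for arg in render_cli(spec)))

# The two column-numerical parameters (x and y axes) are the only required
# ones; input_log offers the four axis-log choices with "" (linear) default.
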