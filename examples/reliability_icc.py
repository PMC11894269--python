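"""Intrarater reliability of repeated sphere radii.

Loads the packaged table of 15 dental models whose Monson-sphere radius
was measured in two sessions by the same operator, and computes the
single-measures intraclass correlation under both two-way forms.  Values
near 1 mean the radius measurement is highly repeatable; the consistency
form ICC(3,1) is the package default for a same-operator design.
"""

from monsonsphere import (
    icc_single_measures,
    read_repeated_radii,
    table1_fixture_path,
)

data = read_repeated_radii(table1_fixture_path())
print(f"{data.n_models} models, 2 sessions")

for form in ("ICC(3,1)", "ICC(2,1)"):
    res = icc_single_measures(data, form=form)
    print(
        f"{form}: ICC = {res.icc:.4f}, 95% CI ({res.ci_low:.4f}, "
        f"{res.ci_high:.4f}), F = {res.f_value:.1f}, p = {res.p_value:.2e}"
    )
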