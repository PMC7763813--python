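"""Gene-specific surveillance plans from final test results.

A CDKN2A carrier with familial pancreatic cancer is referred for pancreatic
imaging on top of 3-month skin checks; an MITF carrier gets urinary cytology;
a patient whose only finding is a VUS follows a 6-month re-review schedule;
a negative patient returns to 8-10-month follow-up with re-counselling.
"""

from melpanel.cohort import (
    MELANOMA,
    PANCREATIC,
    ObservedVariant,
    PatientRecord,
    Relative,
    apply_panel,
    surveillance_plan,
    triage,
)


def show(label, patient):
    triage(patient)
    apply_panel(patient)
    print(label)
    for action in surveillance_plan(patient):
        age = f" from age {action.start_age}" if action.start_age else ""
        print(f"    [{action.code}] {action.description}{age}")
    print()


show(
    "CDKN2A carrier, father with pancreatic cancer:",
    PatientRecord(
        id="P1", sex="F", age_first_melanoma=38, n_melanomas=3,
        relatives=[Relative(1, PANCREATIC)], test_year=2018,
        observed_variants=[
            ObservedVariant("CDKN2A", "LP", 101, "p16,p16γ:c.301G>T (p.G101W)")
        ],
    ),
)

show(
    "MITF p.E318K carrier:",
    PatientRecord(
        id="P2", sex="M", age_first_melanoma=45, n_melanomas=2,
        relatives=[Relative(2, MELANOMA)], test_year=2018,
        observed_variants=[ObservedVariant("MITF", "P", 318, "MITF:c.952G>A")],
    ),
)

show(
    "BAP1 VUS only:",
    PatientRecord(
        id="P3", sex="F", age_first_melanoma=51, n_melanomas=3, test_year=2018,
        observed_variants=[ObservedVariant("BAP1", "VUS", None, "BAP1:VUS-1")],
    ),
)

show(
    "Negative result:",
    PatientRecord(id="P4", sex="M", age_first_melanoma=60, n_melanomas=2,
                  relatives=[Relative(1, MELANOMA)], test_year=2010),
)
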