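"""From encounter records to a weighted term-by-encounter matrix.

Each encounter contributes field-qualified terms (admitting / principal /
secondary ICD-9-CM codes, gender, discharge status, a binned age term, and
stop-word-filtered free text).  The matrix entries can be binary presence,
raw counts, or tf-idf; tf-idf suppresses terms shared by almost everyone,
which is what lets norm-driven factorizations find diagnostic structure.

Run:  python examples/02_term_matrix.py
"""

import numpy as np

from phenofactor import (EncounterRecord, build_matrix, load_stoplist,
                         tokenize_encounter)

records = [
    EncounterRecord(
        encounter_id="E001", patient_id="P001", gender="male",
        age_years=5.2, discharge_status="home", apr_drg=141,
        admitting_dx=["786.07"], principal_dx=["493.92"],
        secondary_dx=["v175"], free_text="history of asthma"),
    EncounterRecord(
        encounter_id="E002", patient_id="P002", gender="female",
        age_years=4.7, discharge_status="home", apr_drg=141,
        admitting_dx=["786.07"], principal_dx=["493.90"]),
    EncounterRecord(
        encounter_id="E003", patient_id="P003", gender="male",
        age_years=1.5, discharge_status="transfer", apr_drg=144,
        admitting_dx=["786.2"], principal_dx=["786.52"],
        secondary_dx=["486.00", "079.99"]),
]

stops = load_stoplist()
print("tokens of E001:", sorted(tokenize_encounter(records[0],
                                                   stoplist=stops)))

for weighting in ("binary", "tf", "tfidf"):
    tm = build_matrix(records, weighting=weighting, stoplist=stops)
    print(f"\n{weighting} matrix ({len(tm.vocabulary)} terms x "
          f"{len(tm.encounter_ids)} encounters)")
    for term in ("adm:786.07", "disch:home", "sec:v175"):
        row = tm.matrix[tm.vocabulary.index[term]]
        print(f"  {term:<12} {np.round(row, 3)}")
# note how tf-idf reweights presence: the code shared by two of three
# encounters drops to ln(3/2) ~ 0.405 while the unique secondary code
# rises to ln(3) ~ 1.099; a term present in every encounter would get 0
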