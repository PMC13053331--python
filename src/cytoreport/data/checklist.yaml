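# Binary clinical-interpretation attribute checklist.
#
# Each attribute has: a question (what the binary judgment asks), detector
# patterns (regexes applied to normalized interpretation text, with simple
# clause-level negation scope), a marker sentence the deterministic
# reference renderer emits when the attribute is active, and a rule — a
# small predicate expression over the panel ('|' = or, '&' = and) that
# decides activity.  All entries are user-editable; the bundled set covers
# common elements of expert QLP/BSP interpretations plus placeholders.
attributes:
  - attribute_id: b_cell_subset_abnormality
    question: "Does the interpretation describe an abnormality of B-cell subset distribution?"
    patterns: ["abnormal subset distribution"]
    marker: "The B-cell compartment shows abnormal subset distribution."
    rule: "any_abnormal_group:BSP"
  - attribute_id: t_cell_abnormality
    question: "Does the interpretation describe a T-cell abnormality?"
    patterns: ["t cell compartment"]
    marker: "T-cell compartment abnormalities are present."
    rule: "abnormal_family:CD3|abnormal_family:CD4|abnormal_family:CD8"
  - attribute_id: nk_cell_abnormality
    question: "Does the interpretation describe an NK-cell abnormality?"
    patterns: ["nk cell compartment"]
    marker: "NK-cell compartment abnormalities are present."
    rule: "abnormal_family:NK"
  - attribute_id: b_lymphopenia
    question: "Does the interpretation state that B cells are quantitatively reduced?"
    patterns: ["b cell lymphopenia"]
    marker: "B-cell lymphopenia is present."
    rule: "decreased:CD19:count"
  - attribute_id: t_lymphopenia
    question: "Does the interpretation state that T cells are quantitatively reduced?"
    patterns: ["t cell lymphopenia"]
    marker: "T-cell lymphopenia is present."
    rule: "decreased:CD3:count"
  - attribute_id: cd4_lymphopenia
    question: "Does the interpretation state that CD4 T cells are reduced?"
    patterns: ["cd4 lymphopenia"]
    marker: "CD4 lymphopenia is present."
    rule: "decreased:CD4:count"
  - attribute_id: reduced_switched_memory
    question: "Does the interpretation note a contracted switched-memory compartment?"
    patterns: ["switched memory compartment"]
    marker: "The switched-memory compartment is contracted."
    rule: "decreased:SWITCHED_MEMORY:any"
  - attribute_id: reduced_total_memory
    question: "Does the interpretation note a contracted total-memory compartment?"
    patterns: ["total memory compartment"]
    marker: "The total-memory compartment is contracted."
    rule: "decreased:TOTAL_MEMORY:any"
  - attribute_id: increased_transitional
    question: "Does the interpretation note an expansion of transitional forms?"
    patterns: ["transitional forms"]
    marker: "Expansion of transitional forms is noted."
    rule: "increased:TRANSITIONAL:any"
  - attribute_id: expanded_cd21low
    question: "Does the interpretation note an expanded CD21low fraction?"
    patterns: ["cd21low fraction"]
    marker: "An expanded CD21low fraction is noted."
    rule: "increased:CD21LOW:any"
  - attribute_id: plasmablast_expansion
    question: "Does the interpretation note plasmablast expansion?"
    patterns: ["plasmablast expansion"]
    marker: "Plasmablast expansion is noted."
    rule: "increased:PLASMABLASTS:any"
  - attribute_id: cvid_consideration
    question: "Does the interpretation raise common variable immunodeficiency as a consideration?"
    patterns: ["common variable immunodeficiency"]
    marker: "The differential diagnosis includes common variable immunodeficiency."
    rule: "decreased:SWITCHED_MEMORY:any&decreased:CD19:count"
  - attribute_id: recovery_caveat
    question: "Does the interpretation caution that absolute counts may reflect specimen cell recovery?"
    patterns: ["with caution"]
    marker: "Absolute subset counts should be interpreted with caution given specimen cell recovery."
    rule: "pbmc_expected"
  - attribute_id: recommend_immunoglobulins
    question: "Does the interpretation recommend quantitative serum immunoglobulins?"
    patterns: ["serum immunoglobulins"]
    marker: "Quantitative serum immunoglobulins are recommended."
    rule: "decreased:SWITCHED_MEMORY:any|decreased:TOTAL_MEMORY:any"
  - attribute_id: recommend_vaccine_response
    question: "Does the interpretation suggest assessing vaccine response?"
    patterns: ["vaccine response"]
    marker: "Assessment of vaccine response may be informative."
    rule: "decreased:SWITCHED_MEMORY:any&decreased:CD19:count"
  - attribute_id: recommend_repeat_testing
    question: "Does the interpretation suggest repeat testing on a fresh specimen?"
    patterns: ["fresh specimen"]
    marker: "Repeat analysis on a fresh specimen may be considered."
    rule: "pbmc_expected"
  - attribute_id: clinical_correlation
    question: "Does the interpretation recommend clinical correlation?"
    patterns: ["clinical correlation"]
    marker: "Clinical correlation is recommended."
    rule: "any_abnormal"
  - attribute_id: normal_study
    question: "Does the interpretation state that the overall immunophenotype is normal?"
    patterns: ["immunophenotype is within normal limits"]
    marker: "The overall immunophenotype is within normal limits."
    rule: "no_abnormal"
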