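# Liverpool Causality Assessment Tool (LCAT) — decision-graph definition.
#
# The branch structure is a transcription of the translated flow diagram and
# of the original English tool publication.  The published running text of
# the Brazilian-Portuguese validation study prints only a subset of the
# question wordings (the modified-questions table, v1/v2); those strings are
# reproduced verbatim below.  Every node whose wiring or wording is NOT
# directly evidenced by that text is marked "transcription: reconstructed" —
# edit there if a figure-accurate source disagrees.
#
# Outcome scores follow the published ordinal coding:
#   unlikely = 0; possible = 1; probable = 2; definite = 3.
tool: LCAT
start: suspect_adr
outcomes:
  - id: unlikely
    score: 0
    labels: {en: "Unlikely", pt-BR: "Improvável"}
  - id: possible
    score: 1
    labels: {en: "Possible", pt-BR: "Possível"}
  - id: probable
    score: 2
    labels: {en: "Probable", pt-BR: "Provável"}
  - id: definite
    score: 3
    labels: {en: "Definite", pt-BR: "Definida"}
questions:
  - id: suspect_adr
    # Asterisked in the original tool; the asterisks were deliberately kept
    # in the translated version, with an explanatory footnote.
    "yes": drug_before_event
    "no": unlikely
    texts:
      en:
        original: "Do you suspect an adverse drug reaction?"
      pt-BR:
        v1: "Há suspeita de reação adversa a medicamento?"
        v2: "Há suspeita de reação adversa a um medicamento?"
    footnote:
      en: "Suspicion should not rest on drug plasma levels alone; consider any objective evidence of the reaction."  # transcription: reconstructed
      pt-BR: "A suspeita não deve se basear apenas nos níveis plasmáticos do medicamento; considere qualquer evidência objetiva da reação."  # transcription: reconstructed
  - id: drug_before_event
    # transcription: reconstructed (temporality gate; wiring implied by the
    # tool's design: no temporal relationship -> unlikely)
    "yes": alternative_cause
    "no": unlikely
    texts:
      en:
        original: "Was the medicine administered before the event occurred?"
      pt-BR:
        v2: "O medicamento foi administrado antes da ocorrência do evento?"  # transcription: reconstructed
  - id: alternative_cause
    # transcription: reconstructed (confounder gate; a more plausible
    # alternative explanation caps the rating at "possible")
    "yes": possible
    "no": dechallenge
    texts:
      en:
        original: "Is the event more likely to be explained by the underlying disease(s) or by other medicines or interventions?"
      pt-BR:
        v2: "O evento é mais provavelmente explicado pela(s) doença(s) de base ou por outros medicamentos ou intervenções?"  # transcription: reconstructed
  - id: dechallenge
    # transcription: reconstructed (dechallenge gate on the definite/probable arm)
    "yes": rechallenge
    "no": possible
    texts:
      en:
        original: "Did the event improve when the medicine was withdrawn or the dose reduced (dechallenge)?"
      pt-BR:
        v2: "O evento melhorou com a suspensão do medicamento ou com a redução da dose (retirada)?"  # transcription: reconstructed
  - id: rechallenge
    # A positive rechallenge defines the reaction (published discussion:
    # after administration, dechallenge and no alternative cause, a positive
    # rechallenge — or the same event in the patient history — gives
    # "definite").
    "yes": definite
    "no": previous_reaction
    texts:
      en:
        original: "Was there a positive rechallenge?"
      pt-BR:
        v1: "Houve reexposição positiva?"
        v2: "Houve reexposição a uma dose subsequente com observação do mesmo evento?"
  - id: previous_reaction
    "yes": definite
    "no": objective_evidence
    texts:
      en:
        original: "Is the same event reported with this medicine in the patient's history?"
      pt-BR:
        v2: "O mesmo evento com este medicamento está relatado na história do paciente?"  # transcription: reconstructed
  - id: objective_evidence
    # transcription: reconstructed (objective-evidence gate separating
    # probable from possible; combines drug-level evidence with other
    # objective evidence of a causal ADR mechanism)
    "yes": probable
    "no": long_lasting
    texts:
      en:
        original: "Is there any objective evidence supporting a causal ADR mechanism?"
      pt-BR:
        v2: "Há alguma evidência objetiva que apoie um mecanismo causal da RAM?"  # transcription: reconstructed
  - id: long_lasting
    # The published translation table prints the English stem with the
    # typographical variant "lost-lasting disability OR impairment"; the
    # original tool's wording "long-lasting" is used here.
    # transcription: position of this node in the flow is reconstructed.
    "yes": probable
    "no": possible
    texts:
      en:
        original: "Was the event associated with long-lasting disability OR impairment?"
      pt-BR:
        v1: "O evento esteve associado a uma disfunção duradoura ou dano?"
        v2: "O evento esteve associado a perda de capacidade duradoura ou dano?"
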