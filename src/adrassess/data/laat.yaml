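# Liverpool Avoidability Assessment Tool (LAAT) — decision-graph definition.
#
# Same transcription caveats as lcat.yaml: the two question wordings printed
# in the published modified-questions table (v1/v2) are verbatim; all other
# nodes are marked "transcription: reconstructed".
#
# Outcome scores follow the published ordinal coding:
#   unassessable = 0; not avoidable = 1; possibly avoidable = 2;
#   definitely avoidable = 3.
tool: LAAT
start: assessable
outcomes:
  - id: unassessable
    score: 0
    labels: {en: "Unassessable", pt-BR: "Não avaliável"}
  - id: not_avoidable
    score: 1
    labels: {en: "Not avoidable", pt-BR: "Não evitável"}
  - id: possibly_avoidable
    score: 2
    labels: {en: "Possibly avoidable", pt-BR: "Possivelmente evitável"}
  - id: definitely_avoidable
    score: 3
    labels: {en: "Definitely avoidable", pt-BR: "Definitivamente evitável"}
questions:
  - id: assessable
    # transcription: reconstructed (information-adequacy gate; an
    # insufficiently documented case cannot be assessed for avoidability)
    "yes": known_strategy
    "no": unassessable
    texts:
      en:
        original: "Does the case report contain sufficient information to assess the avoidability of the ADR?"
      pt-BR:
        v2: "O relato de caso contém informações suficientes para avaliar a evitabilidade da RAM?"  # transcription: reconstructed
  - id: known_strategy
    "yes": strategy_followed
    "no": other_sources
    texts:
      en:
        original: "Was there known preventable strategies and/or appropriate management plan (s), with information about ADR avoidance available?"
      pt-BR:
        v1: "Havia estratégias conhecidas para a prevenção ou plano de manejo apropriado com informações sobre a prevenção da RAM?"
        v2: "Havia estratégias conhecidas para a prevenção ou plano de manejo apropriado contendo informações sobre como evitar a RAM?"
  - id: strategy_followed
    # transcription: reconstructed (ignoring an available, recognised
    # prevention strategy makes the reaction definitely avoidable)
    "yes": not_avoidable
    "no": definitely_avoidable
    texts:
      en:
        original: "Were the known preventive strategies and/or management plan(s) followed appropriately?"
      pt-BR:
        v2: "As estratégias de prevenção conhecidas e/ou o(s) plano(s) de manejo foram seguidos de forma apropriada?"  # transcription: reconstructed
  - id: other_sources
    "yes": measures_taken
    "no": not_avoidable
    texts:
      en:
        original: "Were other information sources, or information in the history available for prevention of the ADR which could have been followed?"
      pt-BR:
        v1: "Outras fontes de informação ou informações no prontuário que poderiam ter sido seguidas estavam disponíveis?"
        v2: "Outras fontes de informação que poderiam ter sido utilizadas para evitar a RAM estavam disponíveis?"
  - id: measures_taken
    # transcription: reconstructed (weaker evidence base than a recognised
    # strategy, hence "possibly" rather than "definitely" avoidable)
    "yes": not_avoidable
    "no": possibly_avoidable
    texts:
      en:
        original: "Were appropriate measures taken in line with the available information?"
      pt-BR:
        v2: "Foram tomadas medidas apropriadas de acordo com as informações disponíveis?"  # transcription: reconstructed
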