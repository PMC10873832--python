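# Surface lexicon for the synthetic clinical-note generator.
#
# Phrases are lowercase and inserted into sentence templates at the
# "{phrase}" slot; the generator records the character span of the phrase
# occurrence as the gold annotation. Modifier cue templates keep the cue in
# the same sentence as the phrase so the "negative qualified" class is
# learnable from local context. Editable: swap phrases or templates without
# touching code.

concept_phrases:
  autonomic_dysfunction:
    - autonomic dysfunction
    - temperature instability
    - excessive sweating episodes
    - autonomic instability
  cerebral_palsy:
    - cerebral palsy
    - spastic quadriplegic cerebral palsy
    - spastic diplegia
  developmental_delay:
    - global developmental delay
    - developmental delay
    - delayed motor milestones
    - speech delay
  epilepsy_or_seizures:
    - seizures
    - epilepsy
    - generalized tonic clonic seizures
    - focal seizures
    - seizure activity
  feeding_issues:
    - feeding difficulties
    - poor oral intake
    - gastrostomy tube feeding
    - oral aversion
  hypotonia:
    - hypotonia
    - low muscle tone
    - truncal hypotonia
    - decreased muscle tone
  insomnia:
    - insomnia
    - difficulty falling asleep
    - frequent night wakings
    - poor sleep maintenance
  mood_disturbance:
    - irritability
    - depressed mood
    - mood lability
    - emotional dysregulation
  movement_disorders:
    - dystonia
    - choreoathetoid movements
    - dystonic posturing
    - athetoid movements
  oculogyric_crisis:
    - oculogyric crisis
    - sustained upward eye deviation
    - oculogyric episodes
  aadcd_mention:
    - aromatic l-amino acid decarboxylase deficiency
    - aadc deficiency

positive_templates:
  - "Patient demonstrates {phrase} on exam."
  - "Exam is notable for {phrase} today."
  - "Ongoing {phrase} reported by the family."
  - "She continues to have {phrase} despite therapy."
  - "History remains significant for {phrase}."

negated_templates:
  - "No evidence of {phrase} on exam today."
  - "The family denies any {phrase} at this visit."
  - "There is no {phrase} noted during the study."
  - "Negative for {phrase} on review of systems."

hypothetical_templates:
  - "Return to clinic promptly if {phrase} develops."
  - "We will monitor closely for {phrase} going forward."
  - "The risk of future {phrase} was discussed with the family."

not_patient_templates:
  - "Mother has a history of {phrase} herself."
  - "Family history is significant for {phrase} in a sibling."
  - "Father reports longstanding {phrase} of his own."

filler_sentences:
  - "Vital signs are stable and within normal limits."
  - "Patient seen in clinic today for routine follow up."
  - "Plan was reviewed with the family and questions were answered."
  - "Growth parameters are tracking appropriately for age."
  - "Medication list was reviewed and reconciled."
  - "Will follow up again in three months."
  - "Immunizations are up to date per the record."
  - "The remainder of the examination is unremarkable."
  - "School performance was discussed at length."
  - "Referral placed to physical therapy for ongoing support."
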