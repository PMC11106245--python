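# Cohort manifest column dictionary, version 1.
# Serialization is plain CSV (or TSV); dates are ISO-8601, compared at day
# resolution.  One row per serum sample, including bridge aliquots.
version: 1
columns:
  sample_id:
    required: true
    type: string
    description: Unique sample identifier within the table.
  cohort:
    required: true
    type: string
    description: Source cohort (CLIMB-like, EPIC-like, ACP-like).
  batch_id:
    required: true
    type: string
    description: Assay batch / plate the sample was measured in.
  age:
    required: true
    type: number
    unit: years
    description: Patient age at draw; > 0.  Missing for bridge aliquots.
  sex:
    required: true
    type: enum [F, M]
    description: Patient sex.  Missing for bridge aliquots.
  disease_duration:
    required: true
    type: number
    unit: years
    description: Years since MS diagnosis; >= 0.  Missing for bridge aliquots.
  draw_date:
    required: true
    type: date (ISO-8601)
    description: Blood-draw calendar date.
  is_bridge:
    required: true
    type: boolean
    description: True for pooled bridge aliquots re-measured in every batch.
  gd_lesion_count:
    required: false
    type: integer >= 0
    description: Gadolinium-enhancing lesion count from the paired MRI.
      Present together with mri_offset_days or not at all.
  mri_offset_days:
    required: false
    type: integer
    unit: days
    description: Signed draw-minus-MRI offset in days; lesion endpoints only
      trust samples with |offset| <= 30.
  crs:
    required: false
    type: enum [quiescence, exacerbation]
    description: Clinical relapse status at draw.
  arr:
    required: false
    type: number >= 0
    unit: relapses/year
    description: Annualized relapse rate; binarized at <= 0.2 (low) and
      >= 1.0 (high), inclusive bounds.
  bridge_aliquot:
    required: false
    type: string
    description: Identifier of the shared serum pool behind a bridge row.
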