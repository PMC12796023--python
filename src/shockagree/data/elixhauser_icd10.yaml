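# Elixhauser comorbidity categories as ICD-10 code-prefix sets
# (prefix-level adaptation of the Quan et al. ICD-10 coding algorithm;
# codes are compared with dots stripped, case-insensitive).
#
# Each category carries a unit weight by default, so the index is a
# count of distinct comorbidity categories present; weights are
# editable here for weighted variants.
categories:
  - name: congestive_heart_failure
    weight: 1
    prefixes: [I099, I110, I130, I132, I255, I420, I425, I426, I427, I428, I429, I43, I50, P290]
  - name: cardiac_arrhythmias
    weight: 1
    prefixes: [I441, I442, I443, I456, I459, I47, I48, I49, R000, R001, R008, T821, Z450, Z950]
  - name: valvular_disease
    weight: 1
    prefixes: [A520, I05, I06, I07, I08, I091, I098, I34, I35, I36, I37, I38, I39, Q230, Q231, Q232, Q233, Z952, Z953, Z954]
  - name: pulmonary_circulation_disorders
    weight: 1
    prefixes: [I26, I27, I280, I288, I289]
  - name: peripheral_vascular_disorders
    weight: 1
    prefixes: [I70, I71, I731, I738, I739, I771, I790, I792, K551, K558, K559, Z958, Z959]
  - name: hypertension_uncomplicated
    weight: 1
    prefixes: [I10]
  - name: hypertension_complicated
    weight: 1
    prefixes: [I11, I12, I13, I15]
  - name: paralysis
    weight: 1
    prefixes: [G041, G114, G801, G802, G81, G82, G830, G831, G832, G833, G834, G839]
  - name: other_neurological_disorders
    weight: 1
    prefixes: [G10, G11, G12, G13, G20, G21, G22, G254, G255, G312, G318, G319, G32, G35, G36, G37, G40, G41, G931, G934, R470, R56]
  - name: chronic_pulmonary_disease
    weight: 1
    prefixes: [I278, I279, J40, J41, J42, J43, J44, J45, J46, J47, J60, J61, J62, J63, J64, J65, J66, J67, J684, J701, J703]
  - name: diabetes_uncomplicated
    weight: 1
    prefixes: [E100, E101, E109, E110, E111, E119, E130, E131, E139]
  - name: diabetes_complicated
    weight: 1
    prefixes: [E102, E103, E104, E105, E106, E107, E108, E112, E113, E114, E115, E116, E117, E118, E132, E133, E134, E135, E136, E137, E138]
  - name: hypothyroidism
    weight: 1
    prefixes: [E00, E01, E02, E03, E890]
  - name: renal_failure
    weight: 1
    prefixes: [I120, I131, N18, N19, N250, Z490, Z491, Z492, Z940, Z992]
  - name: liver_disease
    weight: 1
    prefixes: [B18, I85, I864, I982, K70, K711, K713, K714, K715, K717, K72, K73, K74, K760, K762, K763, K764, K765, K766, K767, K768, K769, Z944]
  - name: peptic_ulcer_disease
    weight: 1
    prefixes: [K257, K259, K267, K269, K277, K279, K287, K289]
  - name: aids_hiv
    weight: 1
    prefixes: [B20, B21, B22, B24]
  - name: lymphoma
    weight: 1
    prefixes: [C81, C82, C83, C84, C85, C88, C96, C900, C902]
  - name: metastatic_cancer
    weight: 1
    prefixes: [C77, C78, C79, C80]
  - name: solid_tumor_without_metastasis
    weight: 1
    prefixes: [C0, C1, C2, C30, C31, C32, C33, C34, C37, C38, C39, C40, C41, C43, C45, C46, C47, C48, C49, C50, C51, C52, C53, C54, C55, C56, C57, C58, C60, C61, C62, C63, C64, C65, C66, C67, C68, C69, C70, C71, C72, C73, C74, C75, C76, C97]
  - name: rheumatoid_arthritis_collagen
    weight: 1
    prefixes: [L940, L941, L943, M05, M06, M08, M120, M123, M30, M310, M311, M312, M313, M32, M33, M34, M35, M45, M461, M468, M469]
  - name: coagulopathy
    weight: 1
    prefixes: [D65, D66, D67, D68, D691, D693, D694, D695, D696]
  - name: obesity
    weight: 1
    prefixes: [E66]
  - name: weight_loss
    weight: 1
    prefixes: [E40, E41, E42, E43, E44, E45, E46, R634, R64]
  - name: fluid_electrolyte_disorders
    weight: 1
    prefixes: [E222, E86, E87]
  - name: blood_loss_anemia
    weight: 1
    prefixes: [D500]
  - name: deficiency_anemia
    weight: 1
    prefixes: [D508, D509, D51, D52, D53]
  - name: alcohol_abuse
    weight: 1
    prefixes: [F10, E52, G621, K292, K700, K703, K709, T51, Z502, Z714, Z721]
  - name: drug_abuse
    weight: 1
    prefixes: [F11, F12, F13, F14, F15, F16, F18, F19, Z715, Z722]
  - name: psychoses
    weight: 1
    prefixes: [F20, F22, F23, F24, F25, F28, F29, F302, F312]
  - name: depression
    weight: 1
    prefixes: [F204, F313, F314, F32, F33, F341, F412, F432]
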