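vocabulary,source_code,concept_id
GENDER,F,8532
SNOMED-CT,34801009,2000101
SNOMED-CT,19169002,2000102
SNOMED-CT,85116003,2000103
SNOMED-CT,48194001,2000104
SNOMED-CT,38341003,2000105
SNOMED-CT,37618003,2000106
SNOMED-CT,398254007,2000107
SNOMED-CT,198992004,2000108
SNOMED-CT,40801000119106,2000109
SNOMED-CT,22033007,2000110
SNOMED-CT,367494004,2000111
SNOMED-CT,44223004,2000112
SNOMED-CT,106004004,2000113
SNOMED-CT,47821001,2000114
SNOMED-CT,36813001,2000115
SNOMED-CT,415105001,2000116
SNOMED-CT,424441002,2000201
SNOMED-CT,424619006,2000202
SNOMED-CT,268445003,2000203
SNOMED-CT,183452005,2000204
SNOMED-CT,50849002,2000205
SNOMED-CT,305408004,2000206
SNOMED-CT,133906008,2000207
SNOMED-CT,77386006,2000301
CUPS,683500,2000401
CUPS,695100,2000402
CUPS,735000,2000403
CUPS,689200,2000404
CUPS,993102,2000405
CUPS,993504,2000406
CUPS,993130,2000407
CIE-10,O95,2000501
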