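{
 "bulge": [
  null,
  3.8,
  2.8,
  3.2,
  3.6,
  4.0,
  4.4,
  4.6,
  4.7,
  4.8,
  4.9,
  5.0,
  5.1,
  5.2,
  5.3,
  5.4,
  5.4,
  5.5,
  5.5,
  5.6,
  5.7,
  5.7,
  5.8,
  5.8,
  5.8,
  5.9,
  5.9,
  6.0,
  6.0,
  6.0,
  6.1
 ],
 "hairpin": [
  null,
  null,
  null,
  5.4,
  5.6,
  5.7,
  5.4,
  6.0,
  5.5,
  6.4,
  6.5,
  6.6,
  6.7,
  6.8,
  6.9,
  6.9,
  7.0,
  7.1,
  7.1,
  7.2,
  7.2,
  7.3,
  7.3,
  7.4,
  7.4,
  7.5,
  7.5,
  7.5,
  7.6,
  7.6,
  7.7
 ],
 "internal": [
  null,
  null,
  1.0,
  1.0,
  1.1,
  2.0,
  2.0,
  2.1,
  2.3,
  2.4,
  2.5,
  2.6,
  2.7,
  2.8,
  2.9,
  2.9,
  3.0,
  3.1,
  3.1,
  3.2,
  3.3,
  3.3,
  3.4,
  3.4,
  3.5,
  3.5,
  3.5,
  3.6,
  3.6,
  3.7,
  3.7
 ],
 "mismatch_hairpin": {
  "AUAA": -0.3,
  "AUAC": -0.5,
  "AUAG": -0.3,
  "AUAU": -0.5,
  "AUCA": -0.1,
  "AUCC": -0.2,
  "AUCG": -0.1,
  "AUCU": -0.2,
  "AUGA": -1.2,
  "AUGC": -0.5,
  "AUGG": -1.1,
  "AUGU": -0.5,
  "AUUA": -0.1,
  "AUUC": -0.3,
  "AUUG": -0.1,
  "AUUU": -1.2,
  "CGAA": -1.5,
  "CGAC": -1.5,
  "CGAG": -1.4,
  "CGAU": -1.5,
  "CGCA": -1.0,
  "CGCC": -1.1,
  "CGCG": -1.0,
  "CGCU": -0.8,
  "CGGA": -2.3,
  "CGGC": -1.5,
  "CGGG": -2.4,
  "CGGU": -1.5,
  "CGUA": -1.0,
  "CGUC": -1.4,
  "CGUG": -1.0,
  "CGUU": -2.1,
  "GCAA": -1.1,
  "GCAC": -1.5,
  "GCAG": -1.3,
  "GCAU": -1.5,
  "GCCA": -1.1,
  "GCCC": -0.7,
  "GCCG": -1.1,
  "GCCU": -0.5,
  "GCGA": -2.5,
  "GCGC": -1.5,
  "GCGG": -2.2,
  "GCGU": -1.5,
  "GCUA": -1.1,
  "GCUC": -1.0,
  "GCUG": -1.1,
  "GCUU": -1.6,
  "GUAA": 0.2,
  "GUAC": -0.5,
  "GUAG": -0.3,
  "GUAU": -0.5,
  "GUCA": -0.1,
  "GUCC": -0.2,
  "GUCG": -0.1,
  "GUCU": -0.2,
  "GUGA": -1.0,
  "GUGC": -0.5,
  "GUGG": -1.1,
  "GUGU": -0.5,
  "GUUA": -0.1,
  "GUUC": -0.3,
  "GUUG": -0.1,
  "GUUU": -1.0,
  "UAAA": -0.5,
  "UAAC": -0.3,
  "UAAG": -0.5,
  "UAAU": -0.3,
  "UACA": -0.2,
  "UACC": -0.1,
  "UACG": -0.2,
  "UACU": 0.0,
  "UAGA": -1.5,
  "UAGC": -0.3,
  "UAGG": -1.5,
  "UAGU": -0.3,
  "UAUA": -0.2,
  "UAUC": -0.1,
  "UAUG": -0.2,
  "UAUU": -0.9,
  "UGAA": -0.5,
  "UGAC": -0.3,
  "UGAG": -0.6,
  "UGAU": -0.3,
  "UGCA": -0.2,
  "UGCC": -0.1,
  "UGCG": -0.2,
  "UGCU": 0.0,
  "UGGA": -0.9,
  "UGGC": -0.3,
  "UGGG": -1.1,
  "UGGU": -0.3,
  "UGUA": -0.2,
  "UGUC": -0.1,
  "UGUG": -0.2,
  "UGUU": -0.9
 },
 "mismatch_internal": {
  "AUAA": 0.7,
  "AUAC": 0.7,
  "AUAG": -0.1,
  "AUAU": 0.7,
  "AUCA": 0.7,
  "AUCC": 0.7,
  "AUCG": 0.7,
  "AUCU": 0.7,
  "AUGA": -0.3,
  "AUGC": 0.7,
  "AUGG": -0.3,
  "AUGU": 0.7,
  "AUUA": 0.7,
  "AUUC": 0.7,
  "AUUG": 0.7,
  "AUUU": 0.1,
  "CGAA": 0.0,
  "CGAC": 0.0,
  "CGAG": -0.8,
  "CGAU": 0.0,
  "CGCA": 0.0,
  "CGCC": 0.0,
  "CGCG": 0.0,
  "CGCU": 0.0,
  "CGGA": -1.0,
  "CGGC": 0.0,
  "CGGG": -1.0,
  "CGGU": 0.0,
  "CGUA": 0.0,
  "CGUC": 0.0,
  "CGUG": 0.0,
  "CGUU": -0.6,
  "GCAA": 0.0,
  "GCAC": 0.0,
  "GCAG": -0.8,
  "GCAU": 0.0,
  "GCCA": 0.0,
  "GCCC": 0.0,
  "GCCG": 0.0,
  "GCCU": 0.0,
  "GCGA": -1.0,
  "GCGC": 0.0,
  "GCGG": -1.0,
  "GCGU": 0.0,
  "GCUA": 0.0,
  "GCUC": 0.0,
  "GCUG": 0.0,
  "GCUU": -0.6,
  "GUAA": 0.7,
  "GUAC": 0.7,
  "GUAG": -0.1,
  "GUAU": 0.7,
  "GUCA": 0.7,
  "GUCC": 0.7,
  "GUCG": 0.7,
  "GUCU": 0.7,
  "GUGA": -0.3,
  "GUGC": 0.7,
  "GUGG": -0.3,
  "GUGU": 0.7,
  "GUUA": 0.7,
  "GUUC": 0.7,
  "GUUG": 0.7,
  "GUUU": 0.1,
  "UAAA": 0.7,
  "UAAC": 0.7,
  "UAAG": -0.1,
  "UAAU": 0.7,
  "UACA": 0.7,
  "UACC": 0.7,
  "UACG": 0.7,
  "UACU": 0.7,
  "UAGA": -0.3,
  "UAGC": 0.7,
  "UAGG": -0.3,
  "UAGU": 0.7,
  "UAUA": 0.7,
  "UAUC": 0.7,
  "UAUG": 0.7,
  "UAUU": 0.1,
  "UGAA": 0.7,
  "UGAC": 0.7,
  "UGAG": -0.1,
  "UGAU": 0.7,
  "UGCA": 0.7,
  "UGCC": 0.7,
  "UGCG": 0.7,
  "UGCU": 0.7,
  "UGGA": -0.3,
  "UGGC": 0.7,
  "UGGG": -0.3,
  "UGGU": 0.7,
  "UGUA": 0.7,
  "UGUC": 0.7,
  "UGUG": 0.7,
  "UGUU": 0.1
 },
 "ml_closing": 9.3,
 "ml_intern": -0.9,
 "ml_unpaired": 0.0,
 "ninio": 0.6,
 "ninio_max": 3.0,
 "stack": {
  "AUAU": -1.1,
  "AUCG": -2.1,
  "AUGC": -2.2,
  "AUGU": -1.4,
  "AUUA": -0.9,
  "AUUG": -0.6,
  "CGAU": -2.1,
  "CGCG": -2.4,
  "CGGC": -3.3,
  "CGGU": -2.1,
  "CGUA": -2.1,
  "CGUG": -1.4,
  "GCAU": -2.2,
  "GCCG": -3.3,
  "GCGC": -3.4,
  "GCGU": -2.5,
  "GCUA": -2.4,
  "GCUG": -1.5,
  "GUAU": -1.4,
  "GUCG": -2.1,
  "GUGC": -2.5,
  "GUGU": 1.3,
  "GUUA": -1.3,
  "GUUG": -0.5,
  "UAAU": -0.9,
  "UACG": -2.1,
  "UAGC": -2.4,
  "UAGU": -1.3,
  "UAUA": -1.3,
  "UAUG": -1.0,
  "UGAU": -0.6,
  "UGCG": -1.4,
  "UGGC": -1.5,
  "UGGU": -0.5,
  "UGUA": -1.0,
  "UGUG": 0.3
 },
 "terminal_au": 0.5
}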