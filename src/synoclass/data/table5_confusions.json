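{
  "labels": ["N", "Orth.A", "OA", "EA", "RA", "SeA"],
  "note": "Published leave-one-out naive-Bayes confusion matrices; rows = true class, columns = predicted class. A: absolute-density subset CD15/CD68/CD38; B: relative-density subset CD15/CD68/CD38; C: relative subset CD15/CD68 plus TIC.",
  "panels": {
    "A": [
      [14, 1, 0, 0, 0, 0],
      [4, 0, 2, 0, 0, 0],
      [5, 1, 19, 1, 0, 0],
      [0, 0, 0, 4, 6, 0],
      [0, 0, 3, 3, 17, 1],
      [0, 0, 0, 0, 3, 8]
    ],
    "B": [
      [13, 1, 1, 0, 0, 0],
      [3, 1, 1, 1, 0, 0],
      [13, 3, 5, 0, 5, 0],
      [1, 0, 2, 0, 5, 2],
      [0, 0, 5, 0, 18, 1],
      [0, 1, 0, 0, 3, 7]
    ],
    "C": [
      [11, 2, 2, 0, 0, 0],
      [2, 0, 3, 1, 0, 0],
      [6, 1, 17, 0, 2, 0],
      [0, 0, 0, 1, 7, 2],
      [0, 0, 4, 1, 19, 0],
      [0, 0, 0, 1, 3, 7]
    ]
  }
}
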