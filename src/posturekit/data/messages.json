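{
  "en": {
    "LEAN_FORWARD": "please lean forward",
    "LEAN_BACKWARD": "please lean backward",
    "LEAN_LEFT": "please lean to the left",
    "LEAN_RIGHT": "please lean to the right",
    "CONGRATULATION_1": "congratulations, you are back in your best posture",
    "CONGRATULATION_2": "well done, great posture",
    "CONGRATULATION_3": "great job, keep it up",
    "PRAISE_MAINTAINED": "great, you have maintained your best posture",
    "CALIBRATION_DONE": "calibration complete, best posture registered"
  },
  "es": {
    "LEAN_FORWARD": "por favor, inclínese hacia adelante",
    "LEAN_BACKWARD": "por favor, inclínese hacia atrás",
    "LEAN_LEFT": "por favor, inclínese hacia la izquierda",
    "LEAN_RIGHT": "por favor, inclínese hacia la derecha",
    "CONGRATULATION_1": "felicitaciones, ha vuelto a su mejor postura",
    "CONGRATULATION_2": "muy bien, excelente postura",
    "CONGRATULATION_3": "buen trabajo, siga así",
    "PRAISE_MAINTAINED": "genial, ha mantenido su mejor postura",
    "CALIBRATION_DONE": "calibración completada, mejor postura registrada"
  },
  "pt": {
    "LEAN_FORWARD": "por favor, incline-se para a frente",
    "LEAN_BACKWARD": "por favor, incline-se para trás",
    "LEAN_LEFT": "por favor, incline-se para a esquerda",
    "LEAN_RIGHT": "por favor, incline-se para a direita",
    "CONGRATULATION_1": "parabéns, você voltou à sua melhor postura",
    "CONGRATULATION_2": "muito bem, ótima postura",
    "CONGRATULATION_3": "bom trabalho, continue assim",
    "PRAISE_MAINTAINED": "ótimo, você manteve sua melhor postura",
    "CALIBRATION_DONE": "calibração concluída, melhor postura registrada"
  }
}
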