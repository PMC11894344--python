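{
  "schema_version": 1,
  "program_id": "cbt-depression-8mod",
  "treatment_window_days": 56,
  "calibration_note": "Per-item required_completions are a modeling choice: the trial app documents only the program-level minimum of 62 retained interactions and the module/category content layout (8 weekly modules; learning, practice, and logging content; behavioral-activation logging in modules 3-8; mindfulness audio in modules 4-6). The allocation below distributes the 62 across that layout (learning 10, practice 17, logging 35). Items with required_completions 0 are optional content, so over-use beyond the minimum is expressible.",
  "modules": [
    {
      "module_index": 1,
      "label": "Psychoeducation and cognitive restructuring",
      "items": [
        {"content_id": "m1_psychoeducation_reading", "category": "learning", "required_completions": 1},
        {"content_id": "m1_psychoeducation_video", "category": "learning", "required_completions": 1},
        {"content_id": "m1_cognitive_restructuring_reading", "category": "learning", "required_completions": 1},
        {"content_id": "m1_catch_thinking_trap", "category": "practice", "required_completions": 3},
        {"content_id": "m1_evaluate_thoughts", "category": "practice", "required_completions": 2},
        {"content_id": "m1_check_in_with_thoughts", "category": "practice", "required_completions": 0, "library_accessible": true}
      ]
    },
    {
      "module_index": 2,
      "label": "Behavioral monitoring",
      "items": [
        {"content_id": "m2_behavior_mood_reading", "category": "learning", "required_completions": 1},
        {"content_id": "m2_record_activity_mood", "category": "logging", "logging_type": "record_activity_mood", "required_completions": 7}
      ]
    },
    {
      "module_index": 3,
      "label": "SMART goals and behavioral activation",
      "items": [
        {"content_id": "m3_behavioral_activation_reading", "category": "learning", "required_completions": 1},
        {"content_id": "m3_schedule_activity", "category": "logging", "logging_type": "schedule_activity", "required_completions": 4},
        {"content_id": "m3_record_activity_mood", "category": "logging", "logging_type": "record_activity_mood", "required_completions": 3}
      ]
    },
    {
      "module_index": 4,
      "label": "Mindful breathing and behavioral activation",
      "items": [
        {"content_id": "m4_mindfulness_reading", "category": "learning", "required_completions": 1},
        {"content_id": "m4_mindful_breathing_audio", "category": "practice", "required_completions": 1},
        {"content_id": "m4_schedule_activity", "category": "logging", "logging_type": "schedule_activity", "required_completions": 2},
        {"content_id": "m4_record_activity_mood", "category": "logging", "logging_type": "record_activity_mood", "required_completions": 4}
      ]
    },
    {
      "module_index": 5,
      "label": "Grounding and behavioral activation",
      "items": [
        {"content_id": "m5_grounding_reading", "category": "learning", "required_completions": 1},
        {"content_id": "m5_grounding_audio", "category": "practice", "required_completions": 1},
        {"content_id": "m5_schedule_activity", "category": "logging", "logging_type": "schedule_activity", "required_completions": 2},
        {"content_id": "m5_record_activity_mood", "category": "logging", "logging_type": "record_activity_mood", "required_completions": 3}
      ]
    },
    {
      "module_index": 6,
      "label": "Letting go of thoughts and behavioral activation",
      "items": [
        {"content_id": "m6_letting_go_reading", "category": "learning", "required_completions": 1},
        {"content_id": "m6_letting_go_audio", "category": "practice", "required_completions": 1},
        {"content_id": "m6_schedule_activity", "category": "logging", "logging_type": "schedule_activity", "required_completions": 2},
        {"content_id": "m6_record_activity_mood", "category": "logging", "logging_type": "record_activity_mood", "required_completions": 3}
      ]
    },
    {
      "module_index": 7,
      "label": "Core beliefs and self-esteem",
      "items": [
        {"content_id": "m7_core_beliefs_reading", "category": "learning", "required_completions": 1},
        {"content_id": "m7_identify_core_beliefs", "category": "practice", "required_completions": 3},
        {"content_id": "m7_challenge_core_beliefs", "category": "practice", "required_completions": 3}
      ]
    },
    {
      "module_index": 8,
      "label": "Relapse prevention",
      "items": [
        {"content_id": "m8_relapse_prevention_reading", "category": "learning", "required_completions": 1},
        {"content_id": "m8_relapse_plan", "category": "practice", "required_completions": 3},
        {"content_id": "m8_schedule_activity", "category": "logging", "logging_type": "schedule_activity", "required_completions": 2},
        {"content_id": "m8_record_activity_mood", "category": "logging", "logging_type": "record_activity_mood", "required_completions": 3}
      ]
    }
  ]
}
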