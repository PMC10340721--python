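/root/pkg/teststest_racc.py_oracles.pytest_mito_events.pytest_group_stats.pytest_synth_mito.pytest_acceptance.pytest_synth_vesicles.pytest_preprocess.pyconftest.pytest_pipeline_cli.pytest_vesicle_coloc.py    �   �����`���G�q�Q��          �   ����Շ�����;q�Q��                                          �   h���0�w�;�[�q�Q��         �   6���Շ�����;q�Q��          �    ����������/q�Q��         �   ����(�R��4�q�Q��          �   �����������/q�Q��         �   i���f`�aBp�q�Q��          �   6���(�R��4�q�Q��          �   ���u0,��q�Q��          �   ����Շ�����;q�Q��         YmrA?yW S�WYmrA?yW S�W������� �   ��������      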