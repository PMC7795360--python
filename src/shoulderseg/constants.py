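"""Shared vocabulary: task/sub-task label sets, channel layout, sampling rate."""

#: The five functional shoulder tasks (fixed order; ties break toward lower index).
TASKS = ("T1", "T2", "T3", "T4", "T5")

#: The three contiguous sub-task phases of every task, in temporal order.
SUBTASKS = ("A", "B", "C")

#: Sampling frequency of both IMUs, Hz.
FS_HZ = 128

#: Channel layout of a sequence matrix: wrist accelerometer (g), wrist
#: gyroscope (deg/s), then the same for the arm unit.
CHANNELS = (
    "wrist_ax", "wrist_ay", "wrist_az",
    "wrist_gx", "wrist_gy", "wrist_gz",
    "arm_ax", "arm_ay", "arm_az",
    "arm_gx", "arm_gy", "arm_gz",
)

#: Tri-axial sensor blocks within CHANNELS, in feature-layout order.
SENSORS = ("wrist_acc", "wrist_gyro", "arm_acc", "arm_gyro")

#: Column slice of each sensor block in the 12-channel signal matrix.
SENSOR_SLICES = {
    "wrist_acc": slice(0, 3),
    "wrist_gyro": slice(3, 6),
    "arm_acc": slice(6, 9),
    "arm_gyro": slice(9, 12),
}
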